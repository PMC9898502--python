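"""Brute-force recomputation of every session feature, written directly from
the feature definitions as an independent code path.

Only the session data model is imported from the package; no helper from
``popkin.features`` is used.  Everything here favours clarity over speed:
plain Python loops, explicit formulas for mean/median/SD, and exhaustive
scans instead of sorting tricks.
"""

import math


def o_mean(xs):
    return sum(xs) / len(xs) if xs else math.nan


def o_median(xs):
    if not xs:
        return math.nan
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def o_sd(xs):
    if len(xs) < 2:
        return math.nan
    m = o_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def bubble_center(b, t):
    t = min(max(t, b.spawn_t), b.end_t)
    return b.center_x_mm, b.y0_mm - b.speed_mm_s * (t - b.spawn_t)


def dist(p, q):
    return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)


def o_detect_pops(traces, bubbles, cfg):
    """(touch_id, bubble_id, distance) triples by first-principles scan."""
    out = []
    used = set()
    for tr in sorted(traces, key=lambda tr: tr.samples[0].t):
        s0 = tr.samples[0]
        candidates = []
        for b in bubbles:
            if b.bubble_id in used:
                continue
            if not (b.spawn_t <= s0.t <= b.end_t):
                continue
            d = dist((s0.x_mm, s0.y_mm), bubble_center(b, s0.t))
            candidates.append((d, b.spawn_t, b.bubble_id))
        if candidates:
            d, _, bid = min(candidates)
            if d <= cfg.pop_radius_mm:
                out.append((tr.touch_id, bid, d))
                used.add(bid)
    return out


def o_episodes(traces, bubbles, cfg):
    """Target episodes: list of (bubble_id, [touch traces], start, end)."""
    by_id = {b.bubble_id: b for b in bubbles}
    assigned = []
    for tr in sorted(traces, key=lambda tr: tr.samples[0].t):
        s0 = tr.samples[0]
        candidates = []
        for b in bubbles:
            if b.spawn_t <= s0.t <= b.end_t:
                d = dist((s0.x_mm, s0.y_mm), bubble_center(b, s0.t))
                candidates.append((d, b.spawn_t, b.bubble_id))
        if candidates:
            d, _, bid = min(candidates)
            if d <= cfg.targeting_radius_mm:
                assigned.append((tr, bid))
    episodes = []
    for tr, bid in assigned:
        b = by_id[bid]
        if episodes and episodes[-1][0] == bid and not b.end_t < tr.samples[0].t:
            episodes[-1][1].append(tr)
            episodes[-1][3] = min(b.end_t, tr.samples[-1].t)
        else:
            episodes.append([bid, [tr], tr.samples[0].t,
                             min(b.end_t, tr.samples[-1].t)])
    return episodes


def o_running_median(col, win):
    half = win // 2
    out = []
    for i in range(len(col)):
        window = sorted(col[max(0, i - half): i + half + 1])
        n = len(window)
        mid = n // 2
        out.append(window[mid] if n % 2 else (window[mid - 1] + window[mid]) / 2.0)
    return out


def o_highpass_sq(accel, cfg):
    """Squared magnitude of the median-high-passed stream (and its times)."""
    ts = [a.t for a in accel]
    win = int(round(cfg.sensor_rate_hz))
    if win % 2 == 0:
        win += 1
    axm = o_running_median([a.ax for a in accel], win)
    aym = o_running_median([a.ay for a in accel], win)
    azm = o_running_median([a.az for a in accel], win)
    m2 = [
        (a.ax - mx) ** 2 + (a.ay - my) ** 2 + (a.az - mz) ** 2
        for a, mx, my, mz in zip(accel, axm, aym, azm)
    ]
    return ts, m2


def o_force(trace, accel, cfg, precomputed=None):
    """Integral of squared high-passed acceleration magnitude over the touch."""
    t0, t1 = trace.samples[0].t, trace.samples[-1].t
    if t1 == t0:
        return 0.0
    ts, m2 = precomputed if precomputed is not None else o_highpass_sq(accel, cfg)

    def interp(tq):
        if tq <= ts[0]:
            return m2[0]
        if tq >= ts[-1]:
            return m2[-1]
        for i in range(1, len(ts)):
            if ts[i] >= tq:
                w = (tq - ts[i - 1]) / (ts[i] - ts[i - 1])
                return m2[i - 1] * (1 - w) + m2[i] * w
        raise AssertionError

    t0c = min(max(t0, ts[0]), ts[-1])
    t1c = min(max(t1, ts[0]), ts[-1])
    if t1c <= t0c:
        return 0.0
    knots = [t0c] + [t for t in ts if t0c < t < t1c] + [t1c]
    vals = [interp(t) for t in knots]
    total = 0.0
    for i in range(1, len(knots)):
        total += 0.5 * (vals[i] + vals[i - 1]) * (knots[i] - knots[i - 1])
    return total


def o_accuracy_profile(trace, bubble, cfg):
    acc = []
    for s in trace.samples:
        d = dist((s.x_mm, s.y_mm), bubble_center(bubble, s.t))
        beyond = d - cfg.bubble_radius_mm
        if beyond < 0:
            beyond = 0.0
        a = 100.0 * (1.0 - beyond / cfg.accuracy_decay_mm)
        acc.append(a if a > 0 else 0.0)
    return acc


def o_extract_features(record):
    """Independent recomputation of the full session feature vector."""
    cfg = record.config
    traces = sorted(record.touches, key=lambda tr: tr.samples[0].t)
    pops = sorted(record.pops, key=lambda p: p.t)
    by_bubble = {b.bubble_id: b for b in record.bubbles}

    n_touches = len(traces)
    n_pops = len(pops)
    f = {}
    f["number_of_touches"] = float(n_touches)
    f["number_of_pops"] = float(n_pops)
    f["bubble_popping_rate"] = n_pops / n_touches if n_touches else math.nan

    doubles = 0
    for i in range(1, n_touches):
        prev, cur = traces[i - 1], traces[i]
        close_t = cur.samples[0].t - prev.samples[-1].t <= cfg.double_touch_window_s
        close_d = dist((cur.samples[0].x_mm, cur.samples[0].y_mm),
                       (prev.samples[0].x_mm, prev.samples[0].y_mm)) \
            <= cfg.double_touch_radius_mm
        doubles += close_t and close_d
    f["double_touch_rate"] = doubles / n_touches if n_touches else math.nan

    ncols = math.ceil(cfg.screen_width_mm / cfg.exploration_cell_mm)
    nrows = math.ceil(cfg.screen_height_mm / cfg.exploration_cell_mm)
    cells = set()
    for tr in traces:
        for s in tr.samples:
            i = min(int(s.x_mm // cfg.exploration_cell_mm), ncols - 1)
            j = min(int(s.y_mm // cfg.exploration_cell_mm), nrows - 1)
            cells.add((i, j))
    f["screen_exploratory_percentage"] = len(cells) / (ncols * nrows)

    transitions = 0
    repeats = 0
    for a, b in zip(pops, pops[1:]):
        ba, bb = by_bubble[a.bubble_id], by_bubble[b.bubble_id]
        if ba.lane != bb.lane:
            transitions += 1
        if ba.lane == bb.lane and ba.character_id == bb.character_id:
            repeats += 1
    f["number_of_transitions"] = float(transitions)
    f["repeat_percentage"] = repeats / (n_pops - 1) if n_pops >= 2 else math.nan

    durations, lengths, velocities = [], [], []
    for tr in traces:
        dur = tr.samples[-1].t - tr.samples[0].t
        ln = sum(
            dist((a.x_mm, a.y_mm), (b.x_mm, b.y_mm))
            for a, b in zip(tr.samples, tr.samples[1:])
        )
        durations.append(dur)
        lengths.append(ln)
        if dur > 0:
            velocities.append(ln / dur)
    for name, xs in (("touch_duration", durations), ("touch_length", lengths),
                     ("touch_velocity", velocities)):
        f[f"{name}_mean"] = o_mean(xs)
        f[f"{name}_median"] = o_median(xs)
        f[f"{name}_std"] = o_sd(xs)

    if record.accel and traces:
        pre = o_highpass_sq(record.accel, cfg)
        forces = [o_force(tr, record.accel, cfg, precomputed=pre) for tr in traces]
        f["applied_force_mean"] = o_mean(forces)
        f["applied_force_median"] = o_median(forces)
        f["applied_force_std"] = o_sd(forces)
    else:
        f["applied_force_mean"] = math.nan
        f["applied_force_median"] = math.nan
        f["applied_force_std"] = math.nan

    dists = [p.distance_to_center_mm for p in pops]
    f["distance_to_center_mean"] = o_mean(dists)
    f["distance_to_center_median"] = o_median(dists)
    f["distance_to_center_std"] = o_sd(dists)

    episodes = o_episodes(traces, record.bubbles, cfg)
    f["number_of_targeted_bubbles"] = float(len(episodes))
    per_target = [float(len(eps)) for _, eps, _, _ in episodes]
    f["touches_per_target_mean"] = o_mean(per_target)
    f["touches_per_target_std"] = o_sd(per_target)
    times = [end - start for _, _, start, end in episodes]
    f["time_on_target_mean"] = o_mean(times)
    f["time_on_target_median"] = o_median(times)
    f["time_on_target_std"] = o_sd(times)
    freqs = [len(eps) / (end - start)
             for _, eps, start, end in episodes if end - start > 0]
    f["touch_frequency_mean"] = o_mean(freqs)
    f["touch_frequency_median"] = o_median(freqs)
    f["touch_frequency_std"] = o_sd(freqs)

    means, maxes, sds = [], [], []
    for bid, eps, _, _ in episodes:
        for tr in eps:
            acc = o_accuracy_profile(tr, by_bubble[bid], cfg)
            means.append(o_mean(acc))
            maxes.append(max(acc))
            if len(acc) >= 2:
                sds.append(o_sd(acc))
    f["popping_accuracy_mean"] = o_mean(means)
    f["popping_accuracy_median"] = o_median(means)
    f["popping_accuracy_std"] = o_sd(means)
    f["accuracy_variation_mean"] = o_mean(sds)
    f["accuracy_mean_variability"] = o_sd(means)
    f["accuracy_max_variability"] = o_sd(maxes)
    return f
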