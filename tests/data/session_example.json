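{
 "accel": [],
 "age_months": 24.0,
 "bubbles": [
  {
   "bubble_id": "L1B0",
   "center_x_mm": 48.0,
   "character_id": 4,
   "end_reason": "popped",
   "end_t": 3.0,
   "lane": 1,
   "spawn_t": 0.0,
   "speed_mm_s": 20.0,
   "y0_mm": 220.0
  },
  {
   "bubble_id": "L1B1",
   "center_x_mm": 48.0,
   "character_id": 4,
   "end_reason": "popped",
   "end_t": 6.0,
   "lane": 1,
   "spawn_t": 3.0166666666666666,
   "speed_mm_s": 20.0,
   "y0_mm": 220.0
  },
  {
   "bubble_id": "L3B0",
   "center_x_mm": 112.0,
   "character_id": 7,
   "end_reason": "exited",
   "end_t": 11.925,
   "lane": 3,
   "spawn_t": 0.0,
   "speed_mm_s": 20.0,
   "y0_mm": 220.0
  }
 ],
 "clinical_scores": {},
 "config": {
  "accuracy_decay_mm": 18.5,
  "bubble_radius_mm": 18.5,
  "bubble_speed_mm_s": 20.0,
  "double_touch_radius_mm": 10.0,
  "double_touch_window_s": 0.3,
  "exploration_cell_mm": 10.0,
  "min_touches_qc": 3,
  "n_lanes": 5,
  "pop_radius_mm": 18.5,
  "screen_height_mm": 220.0,
  "screen_width_mm": 160.0,
  "sensor_rate_hz": 60.0,
  "session_duration_s": 20.0,
  "spawn_gap_s": 0.0,
  "targeting_radius_mm": 27.75
 },
 "group": "NT",
 "iq": null,
 "meta": {
  "note": "hand-built synthetic example session"
 },
 "pops": [
  {
   "bubble_id": "L1B0",
   "distance_to_center_mm": 2.8284271247461903,
   "t": 3.0,
   "touch_id": "T0"
  },
  {
   "bubble_id": "L1B1",
   "distance_to_center_mm": 3.073181485764281,
   "t": 6.0,
   "touch_id": "T2"
  }
 ],
 "schema_version": 1,
 "session_id": "example_01",
 "touches": [
  {
   "samples": [
    [
     3.0,
     50.0,
     162.0
    ],
    [
     3.0166666666666666,
     50.5,
     162.5
    ],
    [
     3.033333333333333,
     51.0,
     163.0
    ]
   ],
   "touch_id": "T0"
  },
  {
   "samples": [
    [
     4.5,
     140.0,
     40.0
    ],
    [
     4.516666666666667,
     140.5,
     40.5
    ],
    [
     4.533333333333333,
     141.0,
     41.0
    ]
   ],
   "touch_id": "T1"
  },
  {
   "samples": [
    [
     6.0,
     46.0,
     158.0
    ],
    [
     6.016666666666667,
     46.5,
     158.5
    ],
    [
     6.033333333333333,
     47.0,
     159.0
    ]
   ],
   "touch_id": "T2"
  },
  {
   "samples": [
    [
     8.0,
     133.0,
     60.0
    ],
    [
     8.016666666666667,
     133.5,
     60.5
    ],
    [
     8.033333333333333,
     134.0,
     61.0
    ]
   ],
   "touch_id": "T3"
  }
 ]
}
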