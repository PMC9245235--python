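{
 "case_id": "case04",
 "expected": {
  "expected_alert_types": [
   "min_interval_needed"
  ],
  "expected_feasible": true,
  "planted_error_class": "min_interval"
 },
 "patient": {
  "age": 72,
  "conditions": [],
  "sex": "F",
  "weight": 60.0
 },
 "prescription": [
  {
   "dose_amount": 0.25,
   "doses_per_day": 1,
   "drug": "DIGOXIN 0.25 MG"
  },
  {
   "dose_amount": 10.0,
   "doses_per_day": 3,
   "drug": "MYLANTA PLUS"
  }
 ],
 "routine": {
  "busy_intervals": [],
  "meal_times": [
   {
    "label": "breakfast",
    "time": "07:30"
   },
   {
    "label": "lunch",
    "time": "12:30"
   },
   {
    "label": "dinner",
    "time": "19:30"
   }
  ],
  "sleep_time": "22:00",
  "wake_time": "07:00"
 }
}
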