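{
 "case_id": "case06",
 "expected": {
  "expected_alert_types": [
   "overdose"
  ],
  "expected_feasible": true,
  "planted_error_class": "overdose"
 },
 "patient": {
  "age": 2,
  "conditions": [],
  "sex": "M",
  "weight": 13.0
 },
 "prescription": [
  {
   "dose_amount": 200.0,
   "doses_per_day": 1,
   "drug": "AZITHROMYCIN SUSPENSION"
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
  "sleep_time": "20:30",
  "wake_time": "07:30"
 }
}
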