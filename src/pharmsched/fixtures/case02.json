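{
 "case_id": "case02",
 "expected": {
  "expected_alert_types": [],
  "expected_feasible": true,
  "planted_error_class": "daytime_routine"
 },
 "patient": {
  "age": 45,
  "conditions": [],
  "sex": "M",
  "weight": 80.0
 },
 "prescription": [
  {
   "dose_amount": 10.0,
   "doses_per_day": 2,
   "drug": "ENALAPRIL 10 MG"
  },
  {
   "dose_amount": 850.0,
   "doses_per_day": 2,
   "drug": "METFORMIN 850 MG"
  }
 ],
 "routine": {
  "busy_intervals": [
   {
    "end": "12:00",
    "label": "work",
    "start": "08:00"
   },
   {
    "end": "18:00",
    "label": "work",
    "start": "13:00"
   }
  ],
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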