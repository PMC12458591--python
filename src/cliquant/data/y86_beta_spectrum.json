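{
 "isotope": "Y-86",
 "comment": "approximate positron branch table; endpoints keV, intensities normalized over beta-plus branches",
 "branches": [
  {
   "endpoint_kev": 1221.0,
   "intensity": 0.5
  },
  {
   "endpoint_kev": 1545.0,
   "intensity": 0.2
  },
  {
   "endpoint_kev": 1988.0,
   "intensity": 0.13
  },
  {
   "endpoint_kev": 2335.0,
   "intensity": 0.09
  },
  {
   "endpoint_kev": 3141.0,
   "intensity": 0.08
  }
 ]
}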