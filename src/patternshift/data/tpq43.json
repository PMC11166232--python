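{
 "scale_min": 0.0,
 "scale_max": 100.0,
 "factors": {
  "WPE": [
   "WPE01",
   "WPE02",
   "WPE03",
   "WPE04",
   "WPE05",
   "WPE06",
   "WPE07"
  ],
  "RFP": [
   "RFP01",
   "RFP02",
   "RFP03",
   "RFP04",
   "RFP05"
  ],
  "TAS": [
   "TAS01",
   "TAS02",
   "TAS03",
   "TAS04",
   "TAS05",
   "TAS06",
   "TAS07"
  ],
  "EPI": [
   "EPI01",
   "EPI02",
   "EPI03",
   "EPI04",
   "EPI05",
   "EPI06",
   "EPI07"
  ],
  "ICP": [
   "ICP01",
   "ICP02",
   "ICP03",
   "ICP04",
   "ICP05",
   "ICP06",
   "ICP07"
  ],
  "MOT": [
   "MOT01",
   "MOT02",
   "MOT03",
   "MOT04",
   "MOT05"
  ],
  "MSC": [
   "MSC01",
   "MSC02",
   "MSC03",
   "MSC04",
   "MSC05"
  ]
 }
}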