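{
 "_comment": "SYNTHETIC DYSF-like transcript model: exon boundaries honour published DYSF c.-coordinate anchors; the rest are invented plausible lengths. Not the real NM_003494.4 exon table.",
 "transcript_id": "SYNTH-DYSF-55",
 "strand": "+",
 "exons": [
  {
   "exon_id": 1,
   "start": 1,
   "end": 88,
   "coding": true
  },
  {
   "exon_id": 2,
   "start": 89,
   "end": 180,
   "coding": true
  },
  {
   "exon_id": 3,
   "start": 181,
   "end": 236,
   "coding": true
  },
  {
   "exon_id": 4,
   "start": 237,
   "end": 342,
   "coding": true
  },
  {
   "exon_id": 5,
   "start": 343,
   "end": 470,
   "coding": true
  },
  {
   "exon_id": 6,
   "start": 471,
   "end": 600,
   "coding": true
  },
  {
   "exon_id": 7,
   "start": 601,
   "end": 730,
   "coding": true
  },
  {
   "exon_id": 8,
   "start": 731,
   "end": 855,
   "coding": true
  },
  {
   "exon_id": 9,
   "start": 856,
   "end": 906,
   "coding": true
  },
  {
   "exon_id": 10,
   "start": 907,
   "end": 1053,
   "coding": true
  },
  {
   "exon_id": 11,
   "start": 1054,
   "end": 1180,
   "coding": true
  },
  {
   "exon_id": 12,
   "start": 1181,
   "end": 1240,
   "coding": true
  },
  {
   "exon_id": 13,
   "start": 1241,
   "end": 1300,
   "coding": true
  },
  {
   "exon_id": 14,
   "start": 1301,
   "end": 1360,
   "coding": true
  },
  {
   "exon_id": 15,
   "start": 1361,
   "end": 1420,
   "coding": true
  },
  {
   "exon_id": 16,
   "start": 1421,
   "end": 1480,
   "coding": true
  },
  {
   "exon_id": 17,
   "start": 1481,
   "end": 1522,
   "coding": true
  },
  {
   "exon_id": 18,
   "start": 1523,
   "end": 1638,
   "coding": true
  },
  {
   "exon_id": 19,
   "start": 1639,
   "end": 1779,
   "coding": true
  },
  {
   "exon_id": 20,
   "start": 1780,
   "end": 1920,
   "coding": true
  },
  {
   "exon_id": 21,
   "start": 1921,
   "end": 2050,
   "coding": true
  },
  {
   "exon_id": 22,
   "start": 2051,
   "end": 2162,
   "coding": true
  },
  {
   "exon_id": 23,
   "start": 2163,
   "end": 2330,
   "coding": true
  },
  {
   "exon_id": 24,
   "start": 2331,
   "end": 2511,
   "coding": true
  },
  {
   "exon_id": 25,
   "start": 2512,
   "end": 2643,
   "coding": true
  },
  {
   "exon_id": 26,
   "start": 2644,
   "end": 2810,
   "coding": true
  },
  {
   "exon_id": 27,
   "start": 2811,
   "end": 3031,
   "coding": true
  },
  {
   "exon_id": 28,
   "start": 3032,
   "end": 3115,
   "coding": true
  },
  {
   "exon_id": 29,
   "start": 3116,
   "end": 3174,
   "coding": true
  },
  {
   "exon_id": 30,
   "start": 3175,
   "end": 3310,
   "coding": true
  },
  {
   "exon_id": 31,
   "start": 3311,
   "end": 3440,
   "coding": true
  },
  {
   "exon_id": 32,
   "start": 3441,
   "end": 3570,
   "coding": true
  },
  {
   "exon_id": 33,
   "start": 3571,
   "end": 3702,
   "coding": true
  },
  {
   "exon_id": 34,
   "start": 3703,
   "end": 3843,
   "coding": true
  },
  {
   "exon_id": 35,
   "start": 3844,
   "end": 3873,
   "coding": true
  },
  {
   "exon_id": 36,
   "start": 3874,
   "end": 3903,
   "coding": true
  },
  {
   "exon_id": 37,
   "start": 3904,
   "end": 4030,
   "coding": true
  },
  {
   "exon_id": 38,
   "start": 4031,
   "end": 4160,
   "coding": true
  },
  {
   "exon_id": 39,
   "start": 4161,
   "end": 4290,
   "coding": true
  },
  {
   "exon_id": 40,
   "start": 4291,
   "end": 4410,
   "coding": true
  },
  {
   "exon_id": 41,
   "start": 4411,
   "end": 4520,
   "coding": true
  },
  {
   "exon_id": 42,
   "start": 4521,
   "end": 4638,
   "coding": true
  },
  {
   "exon_id": 43,
   "start": 4639,
   "end": 4794,
   "coding": true
  },
  {
   "exon_id": 44,
   "start": 4795,
   "end": 4886,
   "coding": true
  },
  {
   "exon_id": 45,
   "start": 4887,
   "end": 5057,
   "coding": true
  },
  {
   "exon_id": 46,
   "start": 5058,
   "end": 5200,
   "coding": true
  },
  {
   "exon_id": 47,
   "start": 5201,
   "end": 5429,
   "coding": true
  },
  {
   "exon_id": 48,
   "start": 5430,
   "end": 5525,
   "coding": true
  },
  {
   "exon_id": 49,
   "start": 5526,
   "end": 5667,
   "coding": true
  },
  {
   "exon_id": 50,
   "start": 5668,
   "end": 5720,
   "coding": true
  },
  {
   "exon_id": 51,
   "start": 5721,
   "end": 5767,
   "coding": true
  },
  {
   "exon_id": 52,
   "start": 5768,
   "end": 5926,
   "coding": true
  },
  {
   "exon_id": 53,
   "start": 5927,
   "end": 6030,
   "coding": true
  },
  {
   "exon_id": 54,
   "start": 6031,
   "end": 6140,
   "coding": true
  },
  {
   "exon_id": 55,
   "start": 6141,
   "end": 6243,
   "coding": true
  }
 ],
 "variable_exons": {
  "17": 0.2
 }
}
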