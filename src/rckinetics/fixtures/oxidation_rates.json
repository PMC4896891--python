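{
 "0.2": {
  "k12": 0.471,
  "k13": 0.0012,
  "k14": 1e-06,
  "k21": 0.9995,
  "k23": 0.000501,
  "k24": 0.00616,
  "k31": 1e-06,
  "k32": 1.1e-06,
  "k34": 1.1e-06,
  "k41": 1e-06,
  "k42": 0.0494,
  "k43": 0.0549
 },
 "0.5": {
  "k12": 1.5085,
  "k13": 0.02554,
  "k14": 1e-06,
  "k21": 1.49375,
  "k23": 0.00077,
  "k24": 0.000159,
  "k31": 0.000751,
  "k32": 0.0487,
  "k34": 0.0217,
  "k41": 1e-06,
  "k42": 1.1e-06,
  "k43": 0.000558
 },
 "1": {
  "k12": 3.94725,
  "k13": 0.01884,
  "k14": 0.007,
  "k21": 1.40738,
  "k23": 0.000601,
  "k24": 0.00535,
  "k31": 0.000139,
  "k32": 1.1e-06,
  "k34": 1.1e-06,
  "k41": 0.00689,
  "k42": 0.111,
  "k43": 0.0583
 },
 "2": {
  "k12": 6.66,
  "k13": 0.01526,
  "k14": 0.024,
  "k21": 1.81312,
  "k23": 0.07201,
  "k24": 1.06e-05,
  "k31": 1.01e-05,
  "k32": 0.15489,
  "k34": 0.00707,
  "k41": 1.03e-05,
  "k42": 1.07e-05,
  "k43": 1.09e-05
 },
 "4": {
  "k12": 23.59125,
  "k13": 0.09032,
  "k14": 0.01974,
  "k21": 6.22,
  "k23": 0.05276,
  "k24": 0.00379,
  "k31": 0.00707,
  "k32": 0.2087,
  "k34": 1.08e-05,
  "k41": 1.03e-05,
  "k42": 1.07e-05,
  "k43": 0.00338
 },
 "6": {
  "k12": 40.8,
  "k13": 1e-05,
  "k14": 0.01981,
  "k21": 15.01,
  "k23": 0.07701,
  "k24": 1.06e-05,
  "k31": 0.016,
  "k32": 0.14101,
  "k34": 0.025,
  "k41": 1.03e-05,
  "k42": 1.07e-05,
  "k43": 1.09e-05
 }
}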