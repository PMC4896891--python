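{
 "0.2": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 0.921,
  "k23": 0.0933,
  "k24": 0.032,
  "k31": 0.0162,
  "k32": 0.0056,
  "k34": 0.0281,
  "k41": 1e-06,
  "k42": 0.00715,
  "k43": 0.00132
 },
 "0.5": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 0.99287,
  "k23": 0.0105,
  "k24": 1.1e-06,
  "k31": 0.000939,
  "k32": 0.024,
  "k34": 1.1e-06,
  "k41": 0.00242,
  "k42": 0.0014,
  "k43": 6.98e-05
 },
 "1": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 0.15523,
  "k23": 1e-06,
  "k24": 0.199,
  "k31": 1.03359,
  "k32": 1.1e-06,
  "k34": 0.000414,
  "k41": 1e-06,
  "k42": 1.1e-06,
  "k43": 0.0045
 },
 "2": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 0.02543,
  "k23": 0.00749,
  "k24": 1.1e-06,
  "k31": 1e-06,
  "k32": 0.00568,
  "k34": 1.1e-06,
  "k41": 1.08e-06,
  "k42": 1.1e-06,
  "k43": 1.1e-06
 },
 "4": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 1.091,
  "k23": 0.00418,
  "k24": 1.1e-06,
  "k31": 0.169,
  "k32": 0.1914,
  "k34": 1.1e-06,
  "k41": 1e-06,
  "k42": 1.1e-06,
  "k43": 0.00374
 },
 "6": {
  "k12": 0,
  "k13": 0,
  "k14": 0,
  "k21": 0.0314,
  "k23": 0.0085,
  "k24": 1.1e-06,
  "k31": 1e-06,
  "k32": 0.0051,
  "k34": 1.1e-06,
  "k41": 1.02,
  "k42": 1.1e-06,
  "k43": 0.0745
 }
}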