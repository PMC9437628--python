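# Repeat-dose regimens for the three intervention drugs.
# Each row: one regimen of repeat_count boluses of `amount`, starting at
# start_time, spaced by `interval` (all times in RTU, amounts in RC).
Etanercept:
  - {start_time: 0.0, amount: 0.1, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.1, amount: 0.2, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.2, amount: 0.4, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.3, amount: 0.6, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.4, amount: 0.8, rate: 1.0, interval: 5.0, repeat_count: 3}
Nivocasan:
  - {start_time: 0.0, amount: 0.1, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.1, amount: 0.2, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.2, amount: 0.4, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.3, amount: 0.6, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.4, amount: 0.8, rate: 1.0, interval: 5.0, repeat_count: 3}
Scyphostatin:
  - {start_time: 0.0, amount: 0.1, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.1, amount: 0.2, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.2, amount: 0.4, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.3, amount: 0.6, rate: 1.0, interval: 5.0, repeat_count: 3}
  - {start_time: 0.4, amount: 0.8, rate: 1.0, interval: 5.0, repeat_count: 3}
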