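icd9,phecode
250.00,250.2
250.02,250.2
250.12,250.21
250.40,250.22
250.42,250.22
250.50,250.23
250.52,250.23
250.60,250.24
250.62,250.24
250.70,250.25
250.72,250.25
250.01,250.1
250.03,250.1
250.11,250.1
250.13,250.1
250.41,250.1
250.51,250.1
250.61,250.1
250.71,250.1
410.00,411.2
410.90,411.2
411.1,411.8
413.9,411.3
414.00,411.4
585.3,585.31
585.4,585.32
585.6,585.34
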