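phecode,exclude_low,exclude_high
250.1,249,250.99
250.2,249,250.99
250.21,249,250.99
250.22,249,250.99
250.23,249,250.99
250.24,249,250.99
250.25,249,250.99
411.2,410,414.99
411.3,410,414.99
411.4,410,414.99
411.8,410,414.99
585.31,580,586.99
585.32,580,586.99
585.34,580,586.99
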