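# Six-node synchronous Boolean network used as the worked example
# throughout the documentation and test suite.  Its two fixed points
# are 000001 and 111010 (node order v1..v6).
targets, factors
v1, v2 & v3
v2, v3
v3, v2 | v4
v4, (v5 & v6) | (!v5 & !v6)
v5, v3
v6, !v5
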