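region	start	end
G-rich loop	858	860
C-helix (approx)	885	890
beta4-beta5 loop (approx)	918	922
E-helix-D-helix loop (approx)	945	955
catalytic loop (approx)	975	985
activation loop	1010	1015
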