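VV  cisphase toy PWM library (synthetic matrices for tests and examples)
XX
//
ID  M_ETS_CORE
BF  ETS family (GGAA core, CGGAAG consensus)
P0      A      C      G      T
01      1      97     1      1      C
02      1      1      97     1      G
03      1      1      97     1      G
04      97     1      1      1      A
05      97     1      1      1      A
06      1      1      97     1      G
XX
//
ID  M_AP4_EBOX
BF  AP-4 style E-box (CAGCTG-like, degenerate first position)
P0      A      C      G      T
01      48     48     2      2      C
02      97     1      1      1      A
03      1      1      97     1      G
04      1      97     1      1      C
05      1      1      1      97     T
06      1      1      97     1      G
XX
//
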