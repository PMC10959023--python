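Hmgb2
Cdk1
Nusap1
Ube2c
Birc5
Tpx2
Top2a
Ndc80
Cks2
Nuf2
Cks1b
Mki67
Tmpo
Cenpf
Tacc3
Smc4
Ccnb2
Ckap2l
Ckap2
Aurkb
Bub1
Kif11
Anp32e
Tubb4b
Gtse1
Kif20b
Hjurp
Cdca3
Cdc20
Ttk
Cdc25c
Kif2c
Rangap1
Ncapd2
Dlgap5
Cdca2
Cdca8
Ect2
Kif23
Hmmr
Aurka
Psrc1
Anln
Lbr
Ckap5
Cenpe
Nek2
G2e3
Gas2l3
Cbx5
Cenpa
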