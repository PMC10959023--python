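cell_type	gene
stem	Lgr5
stem	Ascl2
stem	Olfm4
stem	Slc12a2
stem	Axin2
stem	Gkn3
stem	Smoc2
stem	Hopx
stem	Soat1
stem	Aqp4
enterocyte	Sis
enterocyte	Alpi
enterocyte	Apoa1
enterocyte	Apoa4
enterocyte	Fabp1
enterocyte	Lct
enterocyte	Slc5a1
enterocyte	Ada
enterocyte	Krt20
enterocyte	Slc2a2
paneth	Lyz1
paneth	Defa17
paneth	Defa22
paneth	Defa24
paneth	Ang4
paneth	Mptx2
paneth	Pnliprp2
paneth	Gm14851
paneth	Habp2
paneth	Clps
goblet	Muc2
goblet	Tff3
goblet	Agr2
goblet	Fcgbp
goblet	Clca1
goblet	Zg16
goblet	Tpsg1
goblet	Ccl9
goblet	Galnt12
goblet	Spink4
tuft	Dclk1
tuft	Trpm5
tuft	Gfi1b
tuft	Il25
tuft	Lrmp
tuft	Rgs13
tuft	Ptgs1
tuft	Alox5ap
tuft	Avil
tuft	Hck
eec	Chga
eec	Chgb
eec	Tac1
eec	Tph1
eec	Neurog3
eec	Neurod1
eec	Gcg
eec	Sct
eec	Cck
eec	Gip
immune	Gzma
immune	Gzmb
immune	Itgae
immune	Ccl5
immune	Cd7
immune	Cd69
immune	Cd3g
immune	Cd8a
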