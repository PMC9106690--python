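name,class,measurement_type,internal_standard_id
Ala,amino acids,LC,IS_AA
Gly,amino acids,LC,IS_AA
Ser,amino acids,LC,IS_AA
Val,amino acids,LC,IS_AA
Leu,amino acids,LC,IS_AA
PC_1,phosphatidylcholines,FIA,IS_PC
PC_2,phosphatidylcholines,FIA,IS_PC
PC_3,phosphatidylcholines,FIA,IS_PC
PC_4,phosphatidylcholines,FIA,IS_PC
PC_5,phosphatidylcholines,FIA,IS_PC
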