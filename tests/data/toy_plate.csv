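sample_id,sample_type,condition,replicate,dilution_factor,Ala,Gly,Ser,Val,Leu,PC_1,PC_2,PC_3,PC_4,PC_5,IS_AA,IS_PC
PBS_1,BLANK_PBS,,1,,1000,1000,10000,1000,1000,1000,1000,1000,1000,1000,10000,10000
PBS_2,BLANK_PBS,,2,,1000,1000,20000,1000,1000,1000,1000,1000,1000,1000,10000,10000
PBS_3,BLANK_PBS,,3,,1000,1000,30000,1000,1000,1000,1000,1000,1000,1000,10000,10000
A_r1,SAMPLE,A,1,,100000,50000,50000,40000,30000,40000,15000,30000,30000,30000,10000,10000
A_r2,SAMPLE,A,2,,110000,60000,50000,42000,31000,40000,15000,30000,25000,30000,10000,10000
A_r3,SAMPLE,A,3,,90000,15000,50000,44000,32000,40000,15000,30000,18000,30000,10000,10000
A_r4,SAMPLE,A,4,,105000,15000,50000,46000,33000,40000,15000,18000,19000,30000,10000,10000
A_r5,SAMPLE,A,5,,950000,15000,55000,480000,340000,400000,15000,300000,250000,300000,10000,10000
B_r1,SAMPLE,B,1,,80000,50000,50000,30000,30000,50000,15000,30000,40000,35000,10000,10000
B_r2,SAMPLE,B,2,,85000,55000,50000,35000,31000,50000,15000,30000,40000,35000,10000,10000
B_r3,SAMPLE,B,3,,90000,60000,50000,40000,32000,50000,15000,30000,40000,35000,10000,10000
B_r4,SAMPLE,B,4,,95000,65000,50000,15000,33000,50000,15000,30000,40000,35000,10000,10000
B_r5,SAMPLE,B,5,,100000,70000,50000,15000,34000,50000,15000,30000,40000,35000,10000,10000
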