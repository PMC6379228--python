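study_id,author,year,nationality,gene,snp,allele1,allele2,method,soc,ethnicity,case_11,case_12,case_22,ctrl_11,ctrl_12,ctrl_22,nos_sel,nos_comp,nos_exp
raguema2018,Raguema,2018,Tunisia,Fas,-670 A/G,A,G,PCR-RFLP,HB,Caucasians,105,141,54,151,118,31,3,1,2
masoumi2016,Masoumi,2016,Iran,Fas,-670 A/G,A,G,PCR-RFLP,HB,Caucasians,58,64,31,47,71,22,4,1,2
salimi2014,Salimi,2014,Iran,Fas,-670 A/G,A,G,PCR,HB,Caucasians,27,68,32,64,59,16,3,0,2
nasr2014,Nasr,2014,Egypt,Fas,-670 A/G,A,G,PCR-RFLP,HB,Caucasians,8,30,12,18,25,7,3,1,2
lasabova2014a,Lasabova (1),2014,Slovak,Fas,-670 A/G,A,G,PCR,HB,Caucasians,11,24,11,15,20,10,3,0,2
lasabova2014b,Lasabova (2),2014,Hungaria,Fas,-670 A/G,A,G,PCR,HB,Caucasians,14,39,17,23,36,19,3,0,2
ciarmela2010,Ciarmela,2010,Italy,Fas,-670 A/G,A,G,PCR-RFLP,PB,Caucasians,8,29,13,46,68,28,3,0,2
sziller2009a,Sziller (1),2009,USA,Fas,-670 A/G,A,G,PCR-RFLP,HB,Caucasians,5,15,11,33,37,19,3,0,2
sziller2009b,Sziller (2),2009,USA,Fas,-670 A/G,A,G,PCR-RFLP,HB,Caucasians,2,2,3,33,37,19,3,0,2
raguema2018,Raguema,2018,Tunisia,FasL,124 A/G,A,G,PCR-RFLP,HB,Caucasians,99,145,56,152,117,31,3,1,2
nasr2014,Nasr,2014,Egypt,FasL,124 A/G,A,G,PCR-RFLP,HB,Caucasians,39,7,4,31,15,4,3,1,2
ciarmela2010,Ciarmela,2010,Italy,FasL,124 A/G,A,G,PCR-RFLP,PB,Caucasians,36,12,2,95,38,9,3,0,2
masoumi2016,Masoumi,2016,Iran,FasL,-844 C/T,C,T,PCR-RFLP,HB,Caucasians,58,64,31,70,35,35,3,1,2
salimi2014,Salimi,2014,Iran,FasL,-844 C/T,C,T,PCR,HB,Caucasians,22,69,36,30,83,26,3,0,2
masoumi2016,Masoumi,2016,Iran,Fas,-1377 G/A,G,A,PCR-RFLP,HB,Caucasians,121,28,4,102,38,0,4,1,2
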