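range_start,range_end,group
A00,B99,group_I_infectious_maternal_perinatal
D50,D53,group_I_infectious_maternal_perinatal
E40,E64,group_I_infectious_maternal_perinatal
O00,O99,group_I_infectious_maternal_perinatal
P00,P96,group_I_infectious_maternal_perinatal
C00,D48,group_II_ncd
D55,D89,group_II_ncd
E00,E35,group_II_ncd
E65,E90,group_II_ncd
F00,F99,group_II_ncd
G00,G99,group_II_ncd
H00,H95,group_II_ncd
I00,I99,group_II_ncd
J00,J99,group_II_ncd
K00,K93,group_II_ncd
L00,L99,group_II_ncd
M00,M99,group_II_ncd
N00,N99,group_II_ncd
Q00,Q99,group_II_ncd
S00,T98,group_III_injury
V01,Y98,group_III_injury
R00,R99,other_unclassified
U00,U99,other_unclassified
Z00,Z99,other_unclassified
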