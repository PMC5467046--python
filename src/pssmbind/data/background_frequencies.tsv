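A	0.082238152131
C	0.013639984070
D	0.054360812425
E	0.067104739148
F	0.038430904022
G	0.075467941059
H	0.022600557547
I	0.059139784946
K	0.058044603744
L	0.096276383911
M	0.023994424532
N	0.040422142573
P	0.046794105934
Q	0.039127837515
R	0.055057745918
S	0.065710872162
T	0.053265631223
V	0.068399044205
W	0.010852250100
Y	0.029072082835
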