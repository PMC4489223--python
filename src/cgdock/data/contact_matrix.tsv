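# Pairwise residue contact energies (reduced units).
# Hydrophobicity outer product, negated and scaled; symmetric 20x20.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.1620	-0.2250	0.3150	0.3150	-0.2520	0.0360	0.2880	-0.4050	0.3510	-0.3420	-0.1710	0.3150	0.1440	0.3150	0.4050	0.0720	0.0630	-0.3780	0.0810	0.1170
C	-0.2250	-0.3125	0.4375	0.4375	-0.3500	0.0500	0.4000	-0.5625	0.4875	-0.4750	-0.2375	0.4375	0.2000	0.4375	0.5625	0.1000	0.0875	-0.5250	0.1125	0.1625
D	0.3150	0.4375	-0.6125	-0.6125	0.4900	-0.0700	-0.5600	0.7875	-0.6825	0.6650	0.3325	-0.6125	-0.2800	-0.6125	-0.7875	-0.1400	-0.1225	0.7350	-0.1575	-0.2275
E	0.3150	0.4375	-0.6125	-0.6125	0.4900	-0.0700	-0.5600	0.7875	-0.6825	0.6650	0.3325	-0.6125	-0.2800	-0.6125	-0.7875	-0.1400	-0.1225	0.7350	-0.1575	-0.2275
F	-0.2520	-0.3500	0.4900	0.4900	-0.3920	0.0560	0.4480	-0.6300	0.5460	-0.5320	-0.2660	0.4900	0.2240	0.4900	0.6300	0.1120	0.0980	-0.5880	0.1260	0.1820
G	0.0360	0.0500	-0.0700	-0.0700	0.0560	-0.0080	-0.0640	0.0900	-0.0780	0.0760	0.0380	-0.0700	-0.0320	-0.0700	-0.0900	-0.0160	-0.0140	0.0840	-0.0180	-0.0260
H	0.2880	0.4000	-0.5600	-0.5600	0.4480	-0.0640	-0.5120	0.7200	-0.6240	0.6080	0.3040	-0.5600	-0.2560	-0.5600	-0.7200	-0.1280	-0.1120	0.6720	-0.1440	-0.2080
I	-0.4050	-0.5625	0.7875	0.7875	-0.6300	0.0900	0.7200	-1.0125	0.8775	-0.8550	-0.4275	0.7875	0.3600	0.7875	1.0125	0.1800	0.1575	-0.9450	0.2025	0.2925
K	0.3510	0.4875	-0.6825	-0.6825	0.5460	-0.0780	-0.6240	0.8775	-0.7605	0.7410	0.3705	-0.6825	-0.3120	-0.6825	-0.8775	-0.1560	-0.1365	0.8190	-0.1755	-0.2535
L	-0.3420	-0.4750	0.6650	0.6650	-0.5320	0.0760	0.6080	-0.8550	0.7410	-0.7220	-0.3610	0.6650	0.3040	0.6650	0.8550	0.1520	0.1330	-0.7980	0.1710	0.2470
M	-0.1710	-0.2375	0.3325	0.3325	-0.2660	0.0380	0.3040	-0.4275	0.3705	-0.3610	-0.1805	0.3325	0.1520	0.3325	0.4275	0.0760	0.0665	-0.3990	0.0855	0.1235
N	0.3150	0.4375	-0.6125	-0.6125	0.4900	-0.0700	-0.5600	0.7875	-0.6825	0.6650	0.3325	-0.6125	-0.2800	-0.6125	-0.7875	-0.1400	-0.1225	0.7350	-0.1575	-0.2275
P	0.1440	0.2000	-0.2800	-0.2800	0.2240	-0.0320	-0.2560	0.3600	-0.3120	0.3040	0.1520	-0.2800	-0.1280	-0.2800	-0.3600	-0.0640	-0.0560	0.3360	-0.0720	-0.1040
Q	0.3150	0.4375	-0.6125	-0.6125	0.4900	-0.0700	-0.5600	0.7875	-0.6825	0.6650	0.3325	-0.6125	-0.2800	-0.6125	-0.7875	-0.1400	-0.1225	0.7350	-0.1575	-0.2275
R	0.4050	0.5625	-0.7875	-0.7875	0.6300	-0.0900	-0.7200	1.0125	-0.8775	0.8550	0.4275	-0.7875	-0.3600	-0.7875	-1.0125	-0.1800	-0.1575	0.9450	-0.2025	-0.2925
S	0.0720	0.1000	-0.1400	-0.1400	0.1120	-0.0160	-0.1280	0.1800	-0.1560	0.1520	0.0760	-0.1400	-0.0640	-0.1400	-0.1800	-0.0320	-0.0280	0.1680	-0.0360	-0.0520
T	0.0630	0.0875	-0.1225	-0.1225	0.0980	-0.0140	-0.1120	0.1575	-0.1365	0.1330	0.0665	-0.1225	-0.0560	-0.1225	-0.1575	-0.0280	-0.0245	0.1470	-0.0315	-0.0455
V	-0.3780	-0.5250	0.7350	0.7350	-0.5880	0.0840	0.6720	-0.9450	0.8190	-0.7980	-0.3990	0.7350	0.3360	0.7350	0.9450	0.1680	0.1470	-0.8820	0.1890	0.2730
W	0.0810	0.1125	-0.1575	-0.1575	0.1260	-0.0180	-0.1440	0.2025	-0.1755	0.1710	0.0855	-0.1575	-0.0720	-0.1575	-0.2025	-0.0360	-0.0315	0.1890	-0.0405	-0.0585
Y	0.1170	0.1625	-0.2275	-0.2275	0.1820	-0.0260	-0.2080	0.2925	-0.2535	0.2470	0.1235	-0.2275	-0.1040	-0.2275	-0.2925	-0.0520	-0.0455	0.2730	-0.0585	-0.0845
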