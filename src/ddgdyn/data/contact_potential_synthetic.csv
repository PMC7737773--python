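# SYNTHETIC contact potential (source_id: SYNTH-KD-QC).
# Hydrophobicity-derived quasi-chemical-style stand-in for a statistical
# contact-energy matrix: e_ij = -(kd_i * kd_j)/8. Replace with a real
# AAINDEX contact potential via load_contact_potential()/read_aaindex3().
aa,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
A,-0.4050,1.0125,0.7875,0.7875,-0.5625,0.7875,0.7875,0.0900,0.7200,-1.0125,-0.8550,0.8775,-0.4275,-0.6300,0.3600,0.1800,0.1575,0.2025,0.2925,-0.9450
R,1.0125,-2.5312,-1.9688,-1.9688,1.4062,-1.9688,-1.9688,-0.2250,-1.8000,2.5312,2.1375,-2.1938,1.0687,1.5750,-0.9000,-0.4500,-0.3937,-0.5062,-0.7313,2.3625
N,0.7875,-1.9688,-1.5312,-1.5312,1.0938,-1.5312,-1.5312,-0.1750,-1.4000,1.9688,1.6625,-1.7063,0.8312,1.2250,-0.7000,-0.3500,-0.3062,-0.3937,-0.5687,1.8375
D,0.7875,-1.9688,-1.5312,-1.5312,1.0938,-1.5312,-1.5312,-0.1750,-1.4000,1.9688,1.6625,-1.7063,0.8312,1.2250,-0.7000,-0.3500,-0.3062,-0.3937,-0.5687,1.8375
C,-0.5625,1.4062,1.0938,1.0938,-0.7812,1.0938,1.0938,0.1250,1.0000,-1.4062,-1.1875,1.2188,-0.5938,-0.8750,0.5000,0.2500,0.2188,0.2812,0.4062,-1.3125
Q,0.7875,-1.9688,-1.5312,-1.5312,1.0938,-1.5312,-1.5312,-0.1750,-1.4000,1.9688,1.6625,-1.7063,0.8312,1.2250,-0.7000,-0.3500,-0.3062,-0.3937,-0.5687,1.8375
E,0.7875,-1.9688,-1.5312,-1.5312,1.0938,-1.5312,-1.5312,-0.1750,-1.4000,1.9688,1.6625,-1.7063,0.8312,1.2250,-0.7000,-0.3500,-0.3062,-0.3937,-0.5687,1.8375
G,0.0900,-0.2250,-0.1750,-0.1750,0.1250,-0.1750,-0.1750,-0.0200,-0.1600,0.2250,0.1900,-0.1950,0.0950,0.1400,-0.0800,-0.0400,-0.0350,-0.0450,-0.0650,0.2100
H,0.7200,-1.8000,-1.4000,-1.4000,1.0000,-1.4000,-1.4000,-0.1600,-1.2800,1.8000,1.5200,-1.5600,0.7600,1.1200,-0.6400,-0.3200,-0.2800,-0.3600,-0.5200,1.6800
I,-1.0125,2.5312,1.9688,1.9688,-1.4062,1.9688,1.9688,0.2250,1.8000,-2.5312,-2.1375,2.1938,-1.0687,-1.5750,0.9000,0.4500,0.3937,0.5062,0.7313,-2.3625
L,-0.8550,2.1375,1.6625,1.6625,-1.1875,1.6625,1.6625,0.1900,1.5200,-2.1375,-1.8050,1.8525,-0.9025,-1.3300,0.7600,0.3800,0.3325,0.4275,0.6175,-1.9950
K,0.8775,-2.1938,-1.7063,-1.7063,1.2188,-1.7063,-1.7063,-0.1950,-1.5600,2.1938,1.8525,-1.9012,0.9262,1.3650,-0.7800,-0.3900,-0.3412,-0.4387,-0.6338,2.0475
M,-0.4275,1.0687,0.8312,0.8312,-0.5938,0.8312,0.8312,0.0950,0.7600,-1.0687,-0.9025,0.9262,-0.4512,-0.6650,0.3800,0.1900,0.1662,0.2137,0.3087,-0.9975
F,-0.6300,1.5750,1.2250,1.2250,-0.8750,1.2250,1.2250,0.1400,1.1200,-1.5750,-1.3300,1.3650,-0.6650,-0.9800,0.5600,0.2800,0.2450,0.3150,0.4550,-1.4700
P,0.3600,-0.9000,-0.7000,-0.7000,0.5000,-0.7000,-0.7000,-0.0800,-0.6400,0.9000,0.7600,-0.7800,0.3800,0.5600,-0.3200,-0.1600,-0.1400,-0.1800,-0.2600,0.8400
S,0.1800,-0.4500,-0.3500,-0.3500,0.2500,-0.3500,-0.3500,-0.0400,-0.3200,0.4500,0.3800,-0.3900,0.1900,0.2800,-0.1600,-0.0800,-0.0700,-0.0900,-0.1300,0.4200
T,0.1575,-0.3937,-0.3062,-0.3062,0.2188,-0.3062,-0.3062,-0.0350,-0.2800,0.3937,0.3325,-0.3412,0.1662,0.2450,-0.1400,-0.0700,-0.0612,-0.0788,-0.1137,0.3675
W,0.2025,-0.5062,-0.3937,-0.3937,0.2812,-0.3937,-0.3937,-0.0450,-0.3600,0.5062,0.4275,-0.4387,0.2137,0.3150,-0.1800,-0.0900,-0.0788,-0.1013,-0.1463,0.4725
Y,0.2925,-0.7313,-0.5687,-0.5687,0.4062,-0.5687,-0.5687,-0.0650,-0.5200,0.7313,0.6175,-0.6338,0.3087,0.4550,-0.2600,-0.1300,-0.1137,-0.1463,-0.2113,0.6825
V,-0.9450,2.3625,1.8375,1.8375,-1.3125,1.8375,1.8375,0.2100,1.6800,-2.3625,-1.9950,2.0475,-0.9975,-1.4700,0.8400,0.4200,0.3675,0.4725,0.6825,-2.2050
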