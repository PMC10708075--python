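compound,formula,retention_time_min,cas,chem_class,RS_mean,RS_sd,RR_mean,RR_sd
ethanol,C2H6O,0.444,64-17-5,alcohol,0,0,3.74,1.42
2-nonanol,C9H20O,9.817,628-99-9,alcohol,0.91,0.74,1.10,0.74
α-copaene,C9H11ClO,19.948,1000360-33-0,alcohol,0,0,4.18,3.81
dihydro-β-ionol,C13H24O,22.150,3293-47-8,alcohol,0.43,0.51,0,0
(–)-dihydroedulan ii,C13H22O,17.029,41678-32-4,ether,0.22,0.18,0,0
(E)-2-hexenal,C6H10O,1.150,6728-26-3,aldehyde,47.88,13.87,3.51,0.58
benzaldehyde,C7H6O,5.610,100-52-7,aldehyde,2.71,1.58,0,0
nonanal,C9H18O,10.611,124-19-6,aldehyde,0.81,0.87,1.00,0.63
hexanoic acid,C6H12O2,6.591,142-62-1,acid,11.71,9.80,0,0
"butane-2,3-diyl diacetate",C8H14O4,8.14,1114-92-7,acid,0,0,2.03,1.09
octanoic acid,C8H16O2,13.184,124-07-2,acid,1.61,1.34,1.47,0.99
ethyl butanoate,C6H12O2,0.297,105-54-4,ester,0,0,3.97,8.06
ethyl acetate,C4H8O2,0.751,141-78-6,ester,0,0,14.46,5.7
ethyl tiglate,C7H12O2,4.911,5837-78-5,ester,0,0,0.84,1.34
ethyl hexanoate,C8H16O2,6.774,123-66-0,ester,0,0,5.46,2.89
(3Z)-3-hexen-1-yl acetate,C8H14O2,7.425,3681-71-8,ester,0,0,2.85,1.38
hex-2-enoic acid ethyl ester,C8H14O2,8.352,1552-67-6,ester,0,0,0.18,0.17
sec-heptyl acetate,C9H18O2,8.547,5921-82-4,ester,1.92,0.96,0,0
ethyl benzoate,C9H10O2,13.07,93-89-0,ester,0,0,0.47,0.15
ethyl caprylate,C10H20O2,13.557,106-32-1,ester,0,0,3.44,2.21
methyl salicylate,C8H8O3,13.855,119-36-8,ester,0.46,0.98,0,0
tetradecane,C14H30,20.732,629-59-4,alkane,0.14,0.08,0,0
β-ocimene,C10H16,8.569,3338-55-4,terpenoid,0.94,0.48,0,0
theaspirane,C13H22O,17.306,36431-72-8,terpenoid,0.46,1.33,0,0
α-cubebene,C15H24,18.948,17699-14-8,terpenoid,0.09,0.21,1.47,2.69
ylangene,C15H24,19.805,14912-44-8,terpenoid,0,0,0.11,0.07
α-ionol,C13H22O,20.019,25312-34-9,terpenoid,0.77,0.69,0,0
(–)-β-bourbonene,C15H24,20.131,5208-59-3,terpenoid,0,0,0.30,0.91
germacrene d,C15H24,20.430,23986-74-5,terpenoid,0,0,1.06,1.25
β-copaene,C15H24,20.445,18252-44-3,terpenoid,0,0,1.17,0.33
β-maaliene,C15H24,21.039,489-29-2,terpenoid,0,0,0.18,0.12
(–)-α-gurjunene,C15H24,21.051,489-40-7,terpenoid,0,0,0.56,0.31
caryophyllene,C15H24,21.234,87-44-5,terpenoid,3.56,2.28,0.61,1.62
α-ionone,C13H20O,21.593,127-41-3,terpenoid,0.33,0.26,0,0
(+)-epi-bicyclosesquiphellandrene,C15H24,21.64,54274-73-6,terpenoid,0,0,0.42,0.44
valencene,C15H24,22.111,4630-07-3,terpenoid,1.67,1.60,0.46,2.55
cubenene,C15H24,22.188,16728-99-7,terpenoid,0,0,0.30,0.20
"cis-muurola-4(15),5-diene",C15H24,22.308,157477-72-0,terpenoid,0,0,0.38,0.33
γ-muurolene,C15H24,22.658,30021-74-0,terpenoid,0,0,0.38,0.41
epizonarene,C15H24,23.038,41702-63-0,terpenoid,0,0,1.45,0.44
δ-cadinene,C15H24,23.085,483-76-1,terpenoid,0,0,16.16,8.15
"selina-4,11-dien",C15H24,23.328,103827-22-1,terpenoid,7.83,6.99,7.21,3.15
β-selinene,C15H24,23.414,17066-67-0,terpenoid,1.78,1.38,1.84,0.50
α-vetivenen,C15H22,23.529,28908-26-1,terpenoid,1.02,0.83,0,0
"3,5,11-eudesmatriene",C15H22,23.543,193615-07-5,terpenoid,1.47,0.70,0.85,0.24
α-muurolene,C15H24,23.843,31983-22-9,terpenoid,0,0,2.53,1.84
(r)-γ-cadinene,C15H24,24.262,39029-41-9,terpenoid,0,0,1.11,0.74
(–)-α-panasinsen,C15H24,24.364,56633-28-4,terpenoid,1.37,1.85,2.01,1.35
cadinadiene,C8H4,24.80,29837-12-5,terpenoid,0,0,1.17,0.39
α-agarofuran,C15H24O,25.190,5956-12-7,terpenoid,0.14,0.11,0,0
styrene,C8H8,3.411,100-42-5,aromatic,7.80,1.91,3.75,3.22
4-methoxystyrene,C9H10O,12.353,637-69-4,aromatic,0,0,0.31,0.28
estragole,C10H12O,14.198,140-67-0,aromatic,0,0,1.77,0.89
anethole,C10H12O,17.112,104-46-1,aromatic,0,0,0.30,0.20
α-calacorene,C15H20,25.118,21391-99-1,aromatic,0,0,0.81,0.71
elemicin,C12H16O3,25.495,487-11-6,aromatic,0,0,0.06,0.04
β-calacorene,C15H20,25.712,50277-34-4,aromatic,0,0,0.09,0.05
α-corocalene,C15H20,27.422,20129-39-9,aromatic,0,0,0.09,0.06
cadalin,C15H18,28.887,483-78-3,aromatic,0,0,0.15,0.15
"cis-muurola-3,5-diene",C17H22N4O,22.185,1000365-95-4,other,0,0,0.26,0.19
"Z,Z,Z-1,5,9,9-tetramethyl-1,4,7-cycloundecatriene",C13H10O,22.402,1000062-61-9,other,1.98,2.31,2.01,1.86
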