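name,specificity,glycan_class
ConA,high-mannose,N-linked
LCA,α-D-Man and Fucα-1;6GlcNAc (core fucose),N-linked
PSA,α-D-Man,N-linked
NPA,high-mannose,N-linked
HHL,high-mannose,N-linked
GNA,terminal Manα1-3Man,unspecified
AAL,Fucα1-6GlcNAc (core fucose),N-linked
LTL,Fucα1-2Galβ1-4GlcNAc,both
UEA-I,Fucα1-2Galβ1-4Glc(NAc),both
MAL-I,Galβ-1/4GlcNAc and Siaα2-3Gal,both
MAL-II,Siaα2-3Galβ1-4Glc(NAc)/Glc,both
SNA,Siaα2-6Gal/GalNAc,both
SJA,terminal GalNAc and Gal,both
WGA,multivalent Sia and (GlcNAc)n,both
STL,trimers and tetramers of GlcNAc,both
LEL,(GlcNAc)n and high mannose-type N-glycans,both
DSA,(GlcNAc)n and LacNAc,unspecified
PHA-E,bisecting GlcNAc,N-linked
PHA-E+L,biantennary complex-type N-glycan with outer Gal,N-linked
RCA120,β-Gal and Galβ-1,both
ECA,Galβ1-4GlcNAc (LacNAc),unspecified
BPL,Galβ1-3GalNAc,O-linked
PTL-II,Gal,both
ACA,Galβ1-3GalNAcα-Ser/Thr (T),O-linked
PNA,Galβ1-3GalNAcα (T antigen),unspecified
Jacalin,Galβ1-3GalNAcα-Ser/Thr (T),O-linked
MPL,Galβ1-3GalNAc and GalNAc,O-linked
VVA,terminal GalNAc,O-linked
DBA,αGalNAc and GalNAcα1-3(Fucα1-2)Gal,O-linked
SBA,α/βGalNAc,unspecified
PTL-I,GalNAc,O-linked
WFA,terminal GalNAcα/β1-3/6Gal,O-linked
GSL-I,αGalNAc/αGal,both
BS-I,α-Gal and α-GalNAc,both
EEL,Galα1-3(Fucα1-2)Gal (blood group B),both
GSL-II,terminal GlcNAc,unspecified
PWM,(LacNAc)n,both
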