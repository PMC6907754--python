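code,plant_species,n_pollinator_species,mean_visits_per_encounter,sd_visits_per_encounter,floral_display
TVU,Thymus vulgaris,19,11.3,9.3,576
EFL,Euphorbia flavicoma,17,7.6,7.2,63
MNE,Muscari neglectum,3,7.0,3.7,9
SHI,Sideritis hirsuta,11,6.2,6.8,124
ROF,Rosmarinus officinalis,15,5.6,6.0,502
DHI,Dorycnium hirsutum,25,5.2,5.7,14
GAP,Galium aparine,16,3.9,2.8,294
BLA,Biscutella laevigata,18,2.9,2.5,19
CPA,Centaurea paniculata,28,2.2,1.5,7
ILU,Iris lutescens,4,2.1,1.4,10
OLA,Orobanche latisquama,3,1.9,0.9,62
RGR,Ranunculus gramineus,16,1.8,1.2,3
CAL,Cistus albidus,22,1.7,1.2,10
CSA,Cistus salvifolius,20,1.6,0.9,6
CLI,Centeurea linifolia,25,1.5,0.6,3
LCO,Leuzea conifera,11,1.3,0.5,2
PLY,Phlomis lychnitis,12,1.3,0.4,33
GIL,Gladiolus illyricus,8,1.3,0.3,2
CON,Convolvulus althaeoides,21,1.2,0.4,5
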