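# Mitochondrial karyotypes of parasitic lice (signed dialect).
# species<TAB>karyotype<TAB>provenance
# The elephant-louse record is transcribed from the published minichromosome
# table of its genome report (GenBank KF933032-KF933041).  The anopluran
# records are RECONSTRUCTIONS: minichromosome counts, the four shared derived
# characters, solo-gene features (nad5/rrnS/rrnL), T-nad1-Q cluster
# orientation and unidentified-gene counts follow the published reports;
# gene placements those reports do not constrain were chosen here and must
# not be cited as literature arrangements.
Haematomyzus_elephantis	atp8-atp6-P-cox3,cob-A-W-F-nad6,I-cox1-E,Y-cox2-E,-T--nad1--Q,S2-R-nad4L-M-G-nad3,K-nad4-C,H-nad5,L2-rrnS,L1-rrnL-V	elephant-louse genome report (GenBank KF933032-KF933041)
Haematopinus_suis	I-cox1-Y-cox2-S1,atp8-atp6-P-cox3-N,D-cob-S2-M-nad2,F-nad6-W-A,-T--nad1--Q,R-K-nad4-nad4L-G-nad3,E-H-nad5-C,L1-rrnL,L2-V-rrnS	reconstruction; 9 minichromosomes, character states per published pig-louse genome data
Haematopinus_apri	I-cox1-Y-cox2-S1,atp8-atp6-P-cox3-N,D-cob-S2-M-nad2,F-nad6-W-A,-T--nad1--Q,R-K-nad4-nad4L-G-nad3,E-H-nad5-C,L1-rrnL,L2-V-rrnS	reconstruction; identical karyotype to H. suis per published reports
Polyplax_asiatica	I-cox1-S1,Y-cox2-E,atp8-atp6-P-cox3,W-cob-S2,F-nad6-D-A,-Q--nad1-T-M,K-nad4-C,nad4L-R-nad2-G-nad3,H-nad5,L1-rrnL-V,L2-N-rrnS	reconstruction; 11 minichromosomes incl. the H-nad5 minichromosome, per published rat-louse genome data
Polyplax_spinulosa	I-cox1-S1,Y-cox2-E,atp8-atp6-P-cox3,W-cob-S2,F-nad6-D-A,-Q--nad1-T-M,K-nad4,nad4L-R-nad2-G-nad3,C-H-nad5,rrnL-V-L1,L2-N-rrnS	reconstruction; 11 minichromosomes, character states per published rat-louse genome data
Pthirus_pubis	I-cox1,Y-cox2,atp8-atp6,P-cox3,cob-S2,F-nad6-W-A,-T--nad1-M,Q-nad2-S1,G-nad3-C,R-nad4L,nad5-E,rrnL-L1,L2-rrnS,K-H-V	reconstruction; 14 minichromosomes, 34 genes identified (nad4 and two tRNAs not identified), per published pubic-louse genome data
Pediculus_humanus_capitis	I-cox1,Y-cox2,P-cox3,atp8-atp6,D-cob,F-nad6,-nad1-T,Q-nad2-S1,G-nad3-W,K-nad4,nad4L-R,nad5-C,L1-rrnL,L2-rrnS,E-V,M,A,H,N,S2	reconstruction; 20 minichromosomes, character states per published human-louse genome data
Pediculus_humanus_humanus	I-cox1,Y-cox2,P-cox3,atp8-atp6,D-cob,F-nad6,-nad1-T,Q-nad2-S1,G-nad3-W,K-nad4,nad4L-R,nad5-C,L1-rrnL,L2-rrnS,E-V,M,A,H,N,S2	reconstruction; identical karyotype to the head louse per published reports
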