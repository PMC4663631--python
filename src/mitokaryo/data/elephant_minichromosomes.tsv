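# Per-minichromosome lengths of the elephant-louse mitochondrial genome.
# Coding-region lengths from the published minichromosome table; NCR lengths
# are known in full for the four minichromosomes whose amplicons were
# sequenced to high coverage (empty field = NCR length not determined).
# label<TAB>coding_bp<TAB>ncr_bp
atp8-atp6-P-cox3	1754
cob-A-W-F-nad6	1879
I-cox1-E	1707	2324
Y-cox2-E	857
T-nad1-Q	1143	2457
S2-R-nad4L-M-G-nad3	968
K-nad4-C	1528	2348
H-nad5	1795	2359
L2-rrnS	961
L1-rrnL-V	1436
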