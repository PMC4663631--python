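# Pancrustacean/insect single-chromosome mitochondrial ground pattern
# (Drosophila-type), in physical map order on the reference strand starting
# immediately after the control region.  A leading '-' marks a minus-strand
# gene.  The control region sits between the last and first token and breaks
# gene adjacency like a minichromosome NCR.
I--Q-M-nad2-W--C--Y-cox1-L2-cox2-K-D-atp8-atp6-cox3-G-nad3-A-R-N-S1-E--F--nad5--H--nad4--nad4L-T--P-nad6-cob-S2--nad1--L1--rrnL--V--rrnS
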