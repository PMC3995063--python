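gene_id,amplicon,primer_name,direction,sequence
DCC,proximal,DCC-INT5-FW,forward,acccgtcaccttcttttcct
DCC,proximal,DCC-INT5-RV,reverse,caccgtgccctattttgtct
DCC,distal,DCC-INT13-FW,forward,aaaaacgcagtacggcaact
DCC,distal,DCC-INT13-RV,reverse,tgggatgggttctttctcag
PDZD2,proximal,PDZD2-INT3-FW,forward,gtgagaccctgtccctacca
PDZD2,proximal,PDZD2-INT3-RV,reverse,gtaaagcaaccatgccacct
PDZD2,distal,PDZD2-EX26-FW,forward,gtcggcctagagaggtcctt
PDZD2,distal,PDZD2-EX26-RV,reverse,catgcaccttgcactgactt
LRRFIP1,proximal,LRRFIP1-INT39-FW,forward,gtcctgcagaaccaaagagc
LRRFIP1,proximal,LRRFIP1-INT39-RV,reverse,aagctttcctgacggtctga
LRRFIP1,distal,LRRFIP1-EX76-FW,forward,cgctggaagtgatgatcaaa
LRRFIP1,distal,LRRFIP1-EX76-RV,reverse,gcttggtaatggcttgtggt
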