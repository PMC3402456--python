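% Indirect inference example: tazarotene is an agonist of RARA, activated
% RARA down-regulates the oncogene EGFR.
drug(tazarotene).
protein(rara).
protein(egfr).
oncogene(egfr). % source=cancer_genes
interaction(tazarotene, induces, rara). % source=drugbank
interaction(rara, inhibits, egfr). % source=text_mining evidence=PMID:11788593
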