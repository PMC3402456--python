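% Contradiction example: cladribine is an agonist of PNP, and PNP is involved
% in the cancer-promoting process positive regulation of cell proliferation
% (GO:0042102-style membership), so activating PNP would promote the disease.
drug(cladribine).
protein(pnp).
cancer_promoting_bioprocess(pos_reg_cell_proliferation).
interaction(cladribine, induces, pnp). % source=drugbank
relation(pnp, is_associated, pos_reg_cell_proliferation). % source=go
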