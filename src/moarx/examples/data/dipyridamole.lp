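% Direct inference example: dipyridamole inhibits ADA; overexpressed ADA is
% associated with cancer (acute lymphoblastic leukemia).
drug(dipyridamole).
protein(ada).
disease(cancer).
interaction(dipyridamole, inhibits, ada). % source=drugbank
relation(overexpressed(ada), associated_with, cancer). % source=text_mining evidence=PMID:6981287
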