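# Example known bioactive-peptide set for the novelty screen (one sequence
# per line).  AGDDAPR is an oyster-derived peptide already on record in public
# repositories (ACE-inhibitory, antioxidative, lipase- and amylase-inhibitory
# annotations) and is therefore excluded as non-novel.
AGDDAPR
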