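# Allergenic epitope motifs of oyster tropomyosin (Cra g 1) to screen
# candidate peptides against.  One motif per line, plain one-letter residue
# strings; lines starting with '#' are ignored.
#
# This file is an intentionally empty placeholder: supply your own epitope
# list (e.g. exported from an allergen epitope database) before running an
# allergenicity screen that should exclude anything.
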