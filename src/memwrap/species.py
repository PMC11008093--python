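"""Bead species labels shared across the package."""

HEAD = 0
TAIL = 1
RECEPTOR_HEAD = 2
NP_SURFACE = 3
LIGAND = 4

N_SPECIES = 5

SPECIES_NAMES = {
    HEAD: "head",
    TAIL: "tail",
    RECEPTOR_HEAD: "receptor_head",
    NP_SURFACE: "np_surface",
    LIGAND: "ligand",
}

#: one-letter symbols used in XYZ trajectory output
SPECIES_SYMBOLS = {
    HEAD: "H",
    TAIL: "T",
    RECEPTOR_HEAD: "R",
    NP_SURFACE: "N",
    LIGAND: "L",
}
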