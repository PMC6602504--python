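"""Shared constants: amino-acid alphabet, Gα nomenclature, default thresholds."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = 20

GAP_CHARS = frozenset("-.")
#: Ambiguity / non-standard codes mapped to "unknown" (emits background).
AMBIGUOUS_AA = frozenset("BJZXUO")

#: The 11 chimeric Gα identities measurable in the shedding assay.  C-termini
#: identical across paralogues are represented once: GNAQ also stands for
#: GNA11, and GNAI1 for GNAI2/GNAT1/GNAT2/GNAT3.
CHIMERA_GALPHAS = (
    "GNAS", "GNAL",
    "GNAI1", "GNAI3", "GNAO1", "GNAZ",
    "GNAQ", "GNA14", "GNA15",
    "GNA12", "GNA13",
)

#: Gα gene -> family grouping (Gs, Gi/o, Gq/11, G12/13).
GALPHA_FAMILIES = {
    "GNAS": "Gs", "GNAL": "Gs",
    "GNAI1": "Gi/o", "GNAI3": "Gi/o", "GNAO1": "Gi/o", "GNAZ": "Gi/o",
    "GNAQ": "Gq/11", "GNA14": "Gq/11", "GNA15": "Gq/11",
    "GNA12": "G12/13", "GNA13": "G12/13",
}

#: Chimera representative -> paralogues sharing the identical 6-residue C-terminus.
GALPHA_ALIASES = {
    "GNAQ": ("GNAQ", "GNA11"),
    "GNAI1": ("GNAI1", "GNAI2", "GNAT1", "GNAT2", "GNAT3"),
}

#: LogRAi range is [-2, 0]: a 100-fold span in linear relative activity.
LOGRAI_MIN = -2.0
LOGRAI_MAX = 0.0
#: Receptors with LogRAi >= -1.0 are called coupled (boundary inclusive).
LOGRAI_CUTOFF = -1.0

#: Coupling call on predicted probability (strictly greater than).
PROBABILITY_THRESHOLD = 0.5
#: Default shortlist threshold on |ΔP| in mutation design.
DESIGN_THRESHOLD = 0.25

#: Chimeric Gα construction swaps exactly the last 6 backbone residues.
CHIMERA_TAIL_LENGTH = 6

#: Consensus-column rule: minimum non-gap fraction (boundary inclusive).
DEFAULT_SYMFRAC = 0.5
#: Laplace pseudocount on profile emissions and transitions.
DEFAULT_PSEUDOCOUNT = 0.1
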