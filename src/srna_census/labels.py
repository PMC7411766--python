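"""Class labels shared by the cascade, the simulator, and reports."""

MIRNA = "miRNA"
TRNA_RRNA = "tRNA_rRNA"
TE_PIRNA = "TE_piRNA"
MRNA_DERIVED = "mRNA_derived"
UNANNOTATED = "unannotated"
UNMAPPED = "unmapped"

#: Every trimmed read receives exactly one of these.
CLASS_LABELS = (MIRNA, TRNA_RRNA, TE_PIRNA, MRNA_DERIVED, UNANNOTATED, UNMAPPED)

#: Ground-truth class of simulated reads that are random sequence absent
#: from the genome; the classifier should call them UNMAPPED.
UNMAPPABLE = "unmappable"

#: Classes the simulator draws reads from.
SIM_CLASSES = (MIRNA, TRNA_RRNA, TE_PIRNA, MRNA_DERIVED, UNANNOTATED, UNMAPPABLE)


def expected_label(truth_class: str) -> str:
    """Map a simulator ground-truth class to the expected cascade label."""
    return UNMAPPED if truth_class == UNMAPPABLE else truth_class
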