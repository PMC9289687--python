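"""Shared vocabularies and coordinate conventions.

Every interval in memory is 0-based, half-open ``[start, end)`` on the
forward reference axis; input dialects (GFF3 1-based inclusive, BED
0-based half-open) are normalized on read.
"""

CONTEXTS = ("CG", "CHG", "CHH")

FEATURE_KINDS = ("PCG", "lncRNA", "TE")

LNCRNA_SUBKINDS = ("lincRNA", "other")

TE_CLASSES = ("I", "II")

#: Recognized transposable-element orders. Class I are retrotransposons
#: (copy-and-paste), class II are DNA transposons (cut-and-paste);
#: "other" is accepted in either class.
TE_ORDERS = (
    "Gypsy",
    "Copia",
    "LINE",
    "LTR_other",
    "Helitron",
    "hAT",
    "MITE",
    "Stowaway",
    "Harbinger",
    "SINE",
    "other",
)

#: Default class membership used by the simulator and to validate
#: class/order pairings on input.
CLASS_I_ORDERS = frozenset({"Gypsy", "Copia", "LINE", "LTR_other", "SINE", "other"})
CLASS_II_ORDERS = frozenset(
    {"Helitron", "hAT", "MITE", "Stowaway", "Harbinger", "other"}
)

#: Column order of the in-memory cytosine table.
CYTOSINE_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")

#: Column order of the in-memory feature table.
FEATURE_COLUMNS = (
    "id",
    "chrom",
    "start",
    "end",
    "strand",
    "kind",
    "subkind",
    "te_class",
    "te_order",
)
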