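"""Canonical gene vocabulary for metazoan mitogenomes.

The 37 canonical mitochondrial genes (13 protein-coding genes, 22 tRNAs and
2 rRNAs) plus control-region markers, the name-mapping table used when
importing GenBank annotations, and the ancestral insect (Drosophila-type)
gene order against which rearrangements are called.

Strand labels follow the majority/minority convention used in insect
mitogenomics: ``J`` is the majority (plus) strand, ``N`` the minority strand.
"""

from __future__ import annotations

import re

# ---------------------------------------------------------------------------
# Canonical symbols
# ---------------------------------------------------------------------------

PCGS: tuple[str, ...] = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

TRNAS: tuple[str, ...] = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)

RRNAS: tuple[str, ...] = ("rrnL", "rrnS")

CANONICAL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS  # the 37-gene set

CONTROL_MARKERS: tuple[str, ...] = ("CR", "CR1", "CR2")
NONCODING_MARKER = "NCR"

KINDS = ("PCG", "tRNA", "rRNA", "control", "noncoding")

#: single-letter display codes used in cluster names and schematics
TRNA_LETTER = {
    "trnI": "I", "trnQ": "Q", "trnM": "M", "trnW": "W", "trnC": "C",
    "trnY": "Y", "trnL2": "L2", "trnK": "K", "trnD": "D", "trnG": "G",
    "trnA": "A", "trnR": "R", "trnN": "N", "trnS1": "S1", "trnE": "E",
    "trnF": "F", "trnH": "H", "trnT": "T", "trnP": "P", "trnS2": "S2",
    "trnL1": "L1", "trnV": "V",
}


def kind_of(symbol: str) -> str:
    """Return the feature kind for a canonical symbol."""
    if symbol in PCGS:
        return "PCG"
    if symbol in TRNAS:
        return "tRNA"
    if symbol in RRNAS:
        return "rRNA"
    if symbol in CONTROL_MARKERS:
        return "control"
    return "noncoding"


# ---------------------------------------------------------------------------
# Ancestral insect gene order (Drosophila-type ground pattern)
# ---------------------------------------------------------------------------
# Signs: +1 = J strand, -1 = N strand.  The control region sits between rrnS
# and trnI on the circle.

ANCESTRAL_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("ND2", +1), ("trnW", +1),
    ("trnC", -1), ("trnY", -1), ("COX1", +1), ("trnL2", +1), ("COX2", +1),
    ("trnK", +1), ("trnD", +1), ("ATP8", +1), ("ATP6", +1), ("COX3", +1),
    ("trnG", +1), ("ND3", +1), ("trnA", +1), ("trnR", +1), ("trnN", +1),
    ("trnS1", +1), ("trnE", +1), ("trnF", -1), ("ND5", -1), ("trnH", -1),
    ("ND4", -1), ("ND4L", -1), ("trnT", +1), ("trnP", -1), ("ND6", +1),
    ("CYTB", +1), ("trnS2", +1), ("ND1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1), ("CR", +1),
)

#: named tRNA clusters of the ancestral order, the classical rearrangement
#: hotspots of insect mitogenomes
NAMED_CLUSTERS: dict[str, tuple[str, ...]] = {
    "IQM": ("trnI", "trnQ", "trnM"),
    "WCY": ("trnW", "trnC", "trnY"),
    "ARNS1EF": ("trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"),
    "TP": ("trnT", "trnP"),
}


# ---------------------------------------------------------------------------
# GenBank name mapping
# ---------------------------------------------------------------------------

_AA3_TO_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD", "cys": "trnC",
    "gln": "trnQ", "glu": "trnE", "gly": "trnG", "his": "trnH", "ile": "trnI",
    "lys": "trnK", "met": "trnM", "phe": "trnF", "pro": "trnP", "thr": "trnT",
    "trp": "trnW", "tyr": "trnY", "val": "trnV",
}

# direct aliases, lowercase, punctuation stripped
_ALIASES = {
    # PCGs
    "nd2": "ND2", "nad2": "ND2", "nadh2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh3": "ND3",
    "nd5": "ND5", "nad5": "ND5", "nadh5": "ND5",
    "nd4": "ND4", "nad4": "ND4", "nadh4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nadh4l": "ND4L",
    "nd6": "ND6", "nad6": "ND6", "nadh6": "ND6",
    "nd1": "ND1", "nad1": "ND1", "nadh1": "ND1",
    "cox1": "COX1", "coi": "COX1", "co1": "COX1",
    "cox2": "COX2", "coii": "COX2", "co2": "COX2",
    "cox3": "COX3", "coiii": "COX3", "co3": "COX3",
    "atp6": "ATP6", "atpase6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cytochromeb": "CYTB",
    # full product names
    **{f"nadhdehydrogenasesubunit{k}": f"ND{k}".upper()
       for k in ("1", "2", "3", "4", "4l", "5", "6")},
    "cytochromecoxidasesubuniti": "COX1",
    "cytochromecoxidasesubunitii": "COX2",
    "cytochromecoxidasesubunitiii": "COX3",
    "cytochromecoxidasesubunit1": "COX1",
    "cytochromecoxidasesubunit2": "COX2",
    "cytochromecoxidasesubunit3": "COX3",
    "cytochromeoxidasesubuniti": "COX1",
    "cytochromeoxidasesubunitii": "COX2",
    "cytochromeoxidasesubunitiii": "COX3",
    "atpsynthasef0subunit6": "ATP6", "atpsynthasesubunit6": "ATP6",
    "atpsynthasef0subunit8": "ATP8", "atpsynthasesubunit8": "ATP8",
    # rRNAs
    "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL", "16srrna": "rrnL",
    "16sribosomalrna": "rrnL", "largesubunitribosomalrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "12srrna": "rrnS",
    "12sribosomalrna": "rrnS", "smallsubunitribosomalrna": "rrnS",
    # control region
    "cr": "CR", "dloop": "CR", "controlregion": "CR",
    "atrichregion": "CR", "putativecontrolregion": "CR",
    "cr1": "CR1", "controlregion1": "CR1",
    "cr2": "CR2", "controlregion2": "CR2",
    "ncr": "NCR", "noncodingregion": "NCR",
}

for sym in CANONICAL_GENES:
    _ALIASES.setdefault(sym.lower(), sym)


def _squash(name: str) -> str:
    return re.sub(r"[\s_\-()'.]+", "", name.lower())


def map_gene_name(name: str, note: str = "") -> str | None:
    """Map a GenBank gene/product string onto a canonical symbol.

    ``note`` may carry the anticodon or codon-family disambiguation for the
    duplicated leucine/serine tRNAs (e.g. "(UUR)" or "CUN").  Returns ``None``
    when the name cannot be mapped.
    """
    text = f"{name} {note}".lower()
    squashed = _squash(name)
    if squashed in _ALIASES:
        return _ALIASES[squashed]

    m = re.search(r"trna[\s\-_]?([a-z]{3})\b|^([a-z]{3})\s*trna", text)
    aa = None
    if squashed.startswith("trn") and len(squashed) >= 4:
        # MITOS-style trnX / trnL1 symbols
        tail = squashed[3:]
        if tail in ("l1", "l2", "s1", "s2"):
            return "trn" + tail.upper()[0] + tail[1]
        if len(tail) == 1 and ("trn" + tail.upper()) in TRNAS:
            return "trn" + tail.upper()
    if m:
        aa = m.group(1) or m.group(2)
    if aa in _AA3_TO_TRNA:
        return _AA3_TO_TRNA[aa]
    if aa == "leu":
        if re.search(r"uur|taa\b|uaa\b|l2", text):
            return "trnL2"
        if re.search(r"cun|tag\b|uag\b|l1", text):
            return "trnL1"
        return None
    if aa == "ser":
        if re.search(r"agn|agy|gct\b|ucu\b|s1", text):
            return "trnS1"
        if re.search(r"ucn|tga\b|uga\b|s2", text):
            return "trnS2"
        return None
    return None
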