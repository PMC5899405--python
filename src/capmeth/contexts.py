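"""Cytosine sequence-context classification and small sequence helpers.

Plants methylate cytosines in three contexts — CpG, CHG and CHH (H is A, C
or T) — and the context is a property of the reference strand the cytosine
sits on: a forward-strand cytosine is classified from the bases downstream
of it, a reverse-strand cytosine (a reference G) from the bases upstream,
read on the complementary strand.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: context label for cytosines too close to a contig end to classify
TRUNCATED = "truncated"

CONTEXTS = ("CpG", "CHG", "CHH")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (A/C/G/T/N alphabet)."""
    return seq.translate(COMPLEMENT)[::-1]


def classify_context(seq: str, i: int, strand: str) -> str:
    """Classify the methylation context of the cytosine at 0-based ``i``.

    ``strand`` is ``"+"`` for a forward-strand cytosine (``seq[i] == "C"``)
    and ``"-"`` for a reverse-strand one (``seq[i] == "G"``).  Positions
    within two bases of the relevant contig end that cannot be resolved are
    labelled :data:`TRUNCATED`; windows containing non-ACGT characters are
    treated the same way.
    """
    n = len(seq)
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"position {i} is {seq[i]!r}, not C")
        if i + 1 >= n:
            return TRUNCATED
        b1 = seq[i + 1]
        if b1 == "G":
            return "CpG"
        if b1 not in "ACT":
            return TRUNCATED
        if i + 2 >= n:
            return TRUNCATED
        b2 = seq[i + 2]
        if b2 == "G":
            return "CHG"
        if b2 not in "ACT":
            return TRUNCATED
        return "CHH"
    if strand == "-":
        if seq[i] != "G":
            raise ValueError(f"position {i} is {seq[i]!r}, not G")
        if i - 1 < 0:
            return TRUNCATED
        b1 = seq[i - 1]
        if b1 == "C":
            return "CpG"
        if b1 not in "AGT":
            return TRUNCATED
        if i - 2 < 0:
            return TRUNCATED
        b2 = seq[i - 2]
        if b2 == "C":
            return "CHG"
        if b2 not in "AGT":
            return TRUNCATED
        return "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def cytosine_sites(seq: str):
    """Yield ``(pos_1based, strand)`` for every cytosine site in ``seq``.

    Forward-strand cytosines are reference Cs, reverse-strand ones are
    reference Gs (a C on the complementary strand).
    """
    for i, base in enumerate(seq):
        if base == "C":
            yield i + 1, "+"
        elif base == "G":
            yield i + 1, "-"
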