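"""Protease definitions and in-silico enzymatic digestion.

Cut sites are positions *between* residues.  Every supported rule is
decidable from a window of at most two residues before the site and one
residue after it; the widest rule is the trypsin override (no cut at K/P,
but cut at WK/P).  Selenocysteine (``U``) is an ordinary, non-cutting
residue for all enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EnzymeSpec", "ENZYMES", "get_enzyme", "cleavage_sites", "digest"]


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage rule set for one protease.

    ``cut_after``: residues cut on their C-terminal side.
    ``cut_before``: residues cut on their N-terminal side.
    ``suppress_next``: residues after the site that suppress a C-side cut.
    ``override_pairs``: two-residue patterns ending at the site that
    re-enable a suppressed cut (trypsin's WK/P).
    ``max_miscleavage``: default number of permitted miscleavages.
    """

    name: str
    cut_after: frozenset[str] = frozenset()
    cut_before: frozenset[str] = frozenset()
    suppress_next: frozenset[str] = frozenset()
    override_pairs: frozenset[str] = frozenset()
    max_miscleavage: int = 2

    def is_cut(self, before: str, after: str | None) -> bool:
        """Is there a cleavage site between ``before[-1]`` and ``after``?

        ``before`` holds up to two residues immediately preceding the
        site (empty at a sequence start); ``after`` is the residue
        following the site, or ``None`` at a sequence end (no site).
        """
        if before and before[-1] in self.cut_after:
            if after is None:
                return False
            if after in self.suppress_next:
                return len(before) >= 2 and before[-2:] in self.override_pairs
            return True
        if after is not None and after in self.cut_before:
            return True
        return False


ENZYMES: dict[str, EnzymeSpec] = {
    "trypsin": EnzymeSpec(
        name="trypsin",
        cut_after=frozenset("KR"),
        suppress_next=frozenset("P"),
        override_pairs=frozenset({"WK"}),
        max_miscleavage=2,
    ),
    "lysc": EnzymeSpec(name="lysc", cut_after=frozenset("K"), max_miscleavage=2),
    "lysn": EnzymeSpec(name="lysn", cut_before=frozenset("K"), max_miscleavage=2),
    "argc": EnzymeSpec(name="argc", cut_after=frozenset("R"), max_miscleavage=2),
    "gluc": EnzymeSpec(name="gluc", cut_after=frozenset("E"), max_miscleavage=3),
    "aspn": EnzymeSpec(name="aspn", cut_before=frozenset("D"), max_miscleavage=3),
    "chymotrypsin": EnzymeSpec(
        name="chymotrypsin",
        cut_after=frozenset("FWY"),
        suppress_next=frozenset("P"),
        max_miscleavage=4,
    ),
}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {name!r}; supported: {sorted(ENZYMES)}"
        ) from None


def cleavage_sites(aa_seq: str, enzyme: EnzymeSpec) -> list[int]:
    """0-based positions strictly inside ``aa_seq`` where ``enzyme`` cuts."""
    return [
        i
        for i in range(1, len(aa_seq))
        if enzyme.is_cut(aa_seq[max(0, i - 2) : i], aa_seq[i])
    ]


def digest(
    protein: str,
    enzyme: EnzymeSpec,
    max_miscleavage: int | None = None,
    min_length: int = 7,
    max_length: int = 25,
    c_term_known: bool = True,
    left_context: str = "",
) -> set[str]:
    """Peptides from a full digestion of ``protein`` with miscleavages.

    ``c_term_known=False`` marks a protein whose end is a sequence
    truncation rather than a stop codon: peptides ending at the final
    residue are then discarded, because their C-terminal cleavage context
    is unknown ("terminate translation at the last complete peptide").

    ``left_context`` supplies up to two residues preceding ``protein``
    for cut decisions at its first positions; the protein N-terminus is
    still a free peptide boundary.
    """
    if max_miscleavage is None:
        max_miscleavage = enzyme.max_miscleavage
    n = len(protein)
    ctx = left_context[-2:]
    sites = [
        i
        for i in range(1, n)
        if enzyme.is_cut((ctx + protein[:i])[-2:], protein[i])
    ]
    bounds = [0] + sites + [n]
    out: set[str] = set()
    last = len(bounds) - 1
    for bi in range(last):
        start = bounds[bi]
        for bj in range(bi + 1, min(bi + 2 + max_miscleavage, last + 1)):
            end = bounds[bj]
            if end - start > max_length:
                break
            if end - start < min_length:
                continue
            if bj == last and not c_term_known:
                continue
            out.add(protein[start:end])
    return out
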