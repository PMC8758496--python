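"""Canonical miRNA seed-site scanning and allele-differential site calls.

A canonical seed site on an mRNA 3'UTR (read 5'->3') is built around the
reverse complement of miRNA positions 2-7 (the 6mer core).  Flanking
matches refine the class:

* 8mer     — core, plus Watson-Crick match to miRNA position 8 on the
             site's 5' flank, plus an 'A' opposite miRNA position 1 on
             the 3' flank;
* 7mer-m8  — core plus the position-8 match only;
* 7mer-A1  — core plus the 3'-flank A only;
* 6mer     — core alone.

Each core locus is reported once with the highest-priority class
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  G:U wobble pairs are not accepted.
A single 3'UTR variant can create or destroy such a site on one allele —
the mechanism by which a risk allele gains a repressive miRNA site — and
``compare_alleles`` classifies every hit as present on one or both
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MiRNASeq",
    "Haplotype3UTR",
    "SeedSiteHit",
    "AlleleComparison",
    "scan_seed_sites",
    "compare_alleles",
    "as_rna",
    "SITE_LENGTH",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_RNA_ALPHABET = frozenset("ACGU")

# total site span on the UTR, including flanking matches
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def as_rna(seq: str) -> str:
    """Normalize a nucleotide string to uppercase RNA (T -> U).

    Raises ValueError naming the first offending position if any residue
    falls outside {A, C, G, U, T}.
    """
    out = seq.upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in _RNA_ALPHABET:
            raise ValueError(f"invalid nucleotide {seq[i]!r} at position {i + 1}")
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class MiRNASeq:
    """A mature miRNA sequence, 5'->3', positions 1-based from the 5' end."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_rna(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError(f"miRNA {self.id!r} shorter than 8 nt")


@dataclass(frozen=True)
class SeedSiteHit:
    """One classified seed site.  ``utr_start`` is the 1-based position of
    the site's 5'-most nucleotide (for 8mer/7mer-m8 this includes the
    position-8 match, one nt 5' of the core)."""

    mirna_id: str
    site_type: str
    utr_start: int
    allele_presence: str | None = None  # ref_only | alt_only | both

    @property
    def utr_end(self) -> int:
        return self.utr_start + SITE_LENGTH[self.site_type] - 1

    def spans(self, pos: int) -> bool:
        return self.utr_start <= pos <= self.utr_end


@dataclass(frozen=True)
class Haplotype3UTR:
    """Allele-resolved 3'UTR: two sequences differing at exactly one position."""

    gene_id: str
    ref_seq: str
    alt_seq: str
    variant_pos: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_seq", as_rna(self.ref_seq))
        object.__setattr__(self, "alt_seq", as_rna(self.alt_seq))
        object.__setattr__(self, "ref_allele", as_rna(self.ref_allele))
        object.__setattr__(self, "alt_allele", as_rna(self.alt_allele))
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("allele sequences must have equal length")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq))
            if a != b
        ]
        if diffs != [self.variant_pos]:
            raise ValueError(
                f"alleles must differ exactly at variant_pos={self.variant_pos}; "
                f"differences found at {diffs}"
            )
        p = self.variant_pos - 1
        if self.ref_seq[p] != self.ref_allele or self.alt_seq[p] != self.alt_allele:
            raise ValueError("declared alleles do not match the sequences at variant_pos")


def _verify_hit(utr: str, mirna: MiRNASeq, hit: SeedSiteHit) -> None:
    # re-derive the pairing base-by-base; guards against bookkeeping slips
    seq = mirna.sequence
    core = _revcomp(seq[1:7])
    start0 = hit.utr_start - 1
    core0 = start0 + 1 if hit.site_type in ("8mer", "7mer-m8") else start0
    assert utr[core0:core0 + 6] == core, "core mismatch in reported hit"
    if hit.site_type in ("8mer", "7mer-m8"):
        assert utr[start0] == _COMPLEMENT[seq[7]], "m8 mismatch in reported hit"
    if hit.site_type in ("8mer", "7mer-A1"):
        assert utr[core0 + 6] == "A", "A1 mismatch in reported hit"


def scan_seed_sites(utr_seq: str, mirna: MiRNASeq) -> list[SeedSiteHit]:
    """Find and classify every canonical seed site for ``mirna`` on a UTR.

    The UTR may be given as DNA or RNA; it is normalized to RNA sense
    strand 5'->3'.  Returns hits sorted by position; each core locus
    appears once, with its highest-priority class.
    """
    utr = as_rna(utr_seq)
    if len(utr) < 6:
        raise ValueError("UTR shorter than 6 nt cannot contain a seed site")
    seq = mirna.sequence
    core = _revcomp(seq[1:7])       # complements miRNA positions 2-7
    m8 = _COMPLEMENT[seq[7]]        # complements miRNA position 8
    hits: list[SeedSiteHit] = []
    for i in range(len(utr) - 5):
        if utr[i:i + 6] != core:
            continue
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = i if has_m8 else i + 1  # 1-based 5'-most nt of the site
        hit = SeedSiteHit(mirna_id=mirna.id, site_type=site_type, utr_start=start)
        _verify_hit(utr, mirna, hit)
        hits.append(hit)
    return hits


@dataclass
class AlleleComparison:
    """Allele-annotated hits plus the variant-created/destroyed summary."""

    hits: list[SeedSiteHit]
    variant_created: list[SeedSiteHit]    # alt_only, window spans the variant
    variant_destroyed: list[SeedSiteHit]  # ref_only, window spans the variant
    variant_pos: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mirna_id": h.mirna_id,
                    "site_type": h.site_type,
                    "utr_start": h.utr_start,
                    "utr_end": h.utr_end,
                    "allele_presence": h.allele_presence,
                }
                for h in self.hits
            ],
            columns=["mirna_id", "site_type", "utr_start", "utr_end", "allele_presence"],
        )


def compare_alleles(
    hap: Haplotype3UTR, mirnas: Sequence[MiRNASeq] | MiRNASeq
) -> AlleleComparison:
    """Scan both alleles of a 3'UTR and label each hit's allele presence.

    Hits are matched across alleles by (mirna, utr_start, site_type);
    unmatched hits are ``ref_only``/``alt_only``.  Hits whose site window
    spans the variant and exist on one allele only are summarized as
    variant-created (alt_only) or variant-destroyed (ref_only).
    """
    if isinstance(mirnas, MiRNASeq):
        mirnas = [mirnas]
    hits: list[SeedSiteHit] = []
    for mirna in mirnas:
        ref_hits = {(h.mirna_id, h.utr_start, h.site_type) for h in scan_seed_sites(hap.ref_seq, mirna)}
        alt_hits = {(h.mirna_id, h.utr_start, h.site_type) for h in scan_seed_sites(hap.alt_seq, mirna)}
        for key in sorted(ref_hits | alt_hits, key=lambda k: (k[1], k[0], k[2])):
            presence = (
                "both"
                if key in ref_hits and key in alt_hits
                else ("ref_only" if key in ref_hits else "alt_only")
            )
            hits.append(
                SeedSiteHit(
                    mirna_id=key[0],
                    site_type=key[2],
                    utr_start=key[1],
                    allele_presence=presence,
                )
            )
    hits.sort(key=lambda h: (h.utr_start, h.mirna_id, h.site_type))
    created = [h for h in hits if h.allele_presence == "alt_only" and h.spans(hap.variant_pos)]
    destroyed = [h for h in hits if h.allele_presence == "ref_only" and h.spans(hap.variant_pos)]
    return AlleleComparison(
        hits=hits,
        variant_created=created,
        variant_destroyed=destroyed,
        variant_pos=hap.variant_pos,
    )
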