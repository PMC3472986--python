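"""Nucleotide-string helpers for NlaIII/MmeI restriction tags.

A tag is the 4nt NlaIII recognition site (CATG) plus the 17nt that MmeI
releases downstream of it: 21nt total. A site is "extractable" when at least
17nt follow the anchor, so the full 21nt tag fits inside the sequence.
"""

from __future__ import annotations

ANCHOR = "CATG"
TAG_LEN = 21  # 4nt NlaIII anchor + 17nt MmeI cut

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (A<->T, C<->G, N preserved)."""
    return seq.translate(_COMP)[::-1]


def tag_sites(seq: str) -> list[int]:
    """0-based start positions of every extractable CATG site in `seq`."""
    sites = []
    i = seq.find(ANCHOR)
    while i != -1:
        if i + TAG_LEN <= len(seq):
            sites.append(i)
        i = seq.find(ANCHOR, i + 1)
    return sites


def tag_at(seq: str, site: int) -> str:
    """The 21nt tag anchored at `site` (caller guarantees extractability)."""
    return seq[site : site + TAG_LEN]


def three_prime_tag(seq: str) -> str | None:
    """Tag at the 3'-most extractable CATG site, or None if there is none.

    This is the tag the sequencing protocol produces: NlaIII digestion of
    bead-bound cDNA retains the 3'-most fragment, and MmeI releases the 21nt
    tag from its CATG end.
    """
    sites = tag_sites(seq)
    return tag_at(seq, sites[-1]) if sites else None
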