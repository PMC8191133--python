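"""Astacin substrate-specificity scanning over protein sequences.

Astacin-family metalloproteinases cleave preferentially before negatively
charged residues: aspartate at the P1' position (the first residue
C-terminal of the scissile bond), with proline at P2' or P3' further
favouring cleavage.  ``strict`` mode requires D at P1' and P at P2' or P3';
``relaxed`` mode requires only D or E at P1'.  The module also locates the
family's hallmark motifs: the catalytic zinc-binding consensus HExxHxxGxxH,
the Met-turn, and candidate aspartate-switch residues in the pro-domain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

#: family-standard catalytic zinc-binding consensus
ZINC_BINDING_PATTERN = re.compile(r"(?=(HE..H..G..H))")
#: Met-turn signature; fallback relaxes the leading serine
MET_TURN_PATTERN = re.compile(r"(?=(S.M.Y))")
MET_TURN_FALLBACK = re.compile(r"(?=(..M.Y))")
#: pro-domain window (1-based, inclusive) searched for the aspartate switch
DEFAULT_PRODOMAIN_WINDOW = (1, 100)


@dataclass
class CleavageSite:
    """A putative cleavage position (1-based index of the P1' residue)."""

    position: int
    p1_prime: str
    p2_prime: str
    p3_prime: str
    context: str
    score: str  # "strict" | "relaxed"


@dataclass
class MotifHit:
    """A hallmark-motif match (1-based inclusive span)."""

    motif_name: str
    start: int
    end: int
    matched_sequence: str


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"illegal residue {ch!r} at position {i + 1} (1-based); only "
                "the 20 standard one-letter codes and X are accepted")
    return seq


def scan_cleavage_sites(sequence: str, mode: str = "strict"
                        ) -> list[CleavageSite]:
    """Scan a protein sequence for putative astacin cleavage sites.

    The scissile bond lies between positions i-1 and i of a reported site;
    ``position`` is the 1-based index of the P1' residue.  Positions close
    to the C-terminus treat missing P2'/P3' residues as non-matching.
    ``X`` never matches.  Strict sites are a subset of relaxed sites.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    seq = _validate(sequence)
    sites: list[CleavageSite] = []
    for i, residue in enumerate(seq):
        if mode == "strict":
            if residue != "D":
                continue
            p2 = seq[i + 1] if i + 1 < len(seq) else ""
            p3 = seq[i + 2] if i + 2 < len(seq) else ""
            if p2 != "P" and p3 != "P":
                continue
        else:
            if residue not in ("D", "E"):
                continue
            p2 = seq[i + 1] if i + 1 < len(seq) else ""
            p3 = seq[i + 2] if i + 2 < len(seq) else ""
        context = seq[max(0, i - 5):i + 6]
        sites.append(CleavageSite(position=i + 1, p1_prime=residue,
                                  p2_prime=p2, p3_prime=p3, context=context,
                                  score=mode))
    return sites


def find_astacin_motifs(sequence: str,
                        prodomain_window: tuple[int, int] =
                        DEFAULT_PRODOMAIN_WINDOW) -> list[MotifHit]:
    """Locate astacin hallmark motifs; overlapping hits are all reported.

    Zinc-binding sites match HExxHxxGxxH; the Met-turn matches SxMxY, falling
    back to xxMxY only when the strict signature is absent; aspartate-switch
    candidates are aspartates inside the configured pro-domain window.
    """
    seq = _validate(sequence)
    hits: list[MotifHit] = []
    for m in ZINC_BINDING_PATTERN.finditer(seq):
        s = m.start()
        hits.append(MotifHit("zinc-binding", s + 1, s + 11, m.group(1)))
    met_hits = list(MET_TURN_PATTERN.finditer(seq))
    pattern_used = MET_TURN_PATTERN
    if not met_hits:
        met_hits = list(MET_TURN_FALLBACK.finditer(seq))
        pattern_used = MET_TURN_FALLBACK
    del pattern_used
    for m in met_hits:
        s = m.start()
        hits.append(MotifHit("met-turn", s + 1, s + 5, m.group(1)))
    lo, hi = prodomain_window
    window = seq[max(0, lo - 1):hi]
    for i, ch in enumerate(window, start=max(1, lo)):
        if ch == "D":
            hits.append(MotifHit("aspartate-switch", i, i, "D"))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def scan_fasta(path, mode: str = "strict") -> dict[str, list[CleavageSite]]:
    """Scan every record of a protein FASTA file for cleavage sites."""
    results: dict[str, list[CleavageSite]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        results[record.id] = scan_cleavage_sites(str(record.seq), mode=mode)
    return results
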