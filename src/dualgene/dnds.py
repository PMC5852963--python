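"""Pairwise dN/dS by Nei–Gojobori (1986) pathway counting.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the three possible changes at each position that preserve the amino
acid, averaged over the two sequences.  *Differences* between a codon pair
with two or three changed positions are averaged over all substitution
orderings (pathways) with equal weight; pathways passing through a stop
codon are skipped unless every pathway does.  Changes to stop codons count
as nonsynonymous in site counting.  Proportions are corrected for multiple
hits with the Jukes–Cantor formula d = -(3/4)·ln(1 - (4/3)p), which
saturates at p ≥ 3/4.

ω = dN/dS is undefined (None) when dS = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO import parse as _parse_fasta
import numpy as np

_CODE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODE))
_NTS = "ACGT"


class DnDsError(ValueError):
    """Invalid input for dN/dS estimation."""


class SaturationError(DnDsError):
    """Substitution proportion at or beyond the Jukes–Cantor ceiling of 3/4."""


@dataclass(frozen=True)
class DnDsResult:
    dN: float
    dS: float
    omega: float | None
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float


def _codons(seq: str, name: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise DnDsError(f"{name}: length {len(seq)} is not a multiple of 3")
    if not seq:
        raise DnDsError(f"{name}: empty sequence")
    if set(seq) - set(_NTS):
        raise DnDsError(f"{name}: non-ACGT symbols {sorted(set(seq) - set(_NTS))}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if stops:
        raise DnDsError(f"{name}: internal stop codon at codon {stops[0]}")
    return codons


def _syn_sites(codon: str) -> float:
    """Synonymous site count for one codon (0..3)."""
    aa = _CODE[codon]
    syn = 0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            # mutation to a stop codon is a nonsynonymous change
            if mutant not in STOP_CODONS and _CODE[mutant] == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over substitution pathways."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        current = ca
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:  # stop intermediates invalidate the path
                blocked = True
                break
            if _CODE[nxt] == _CODE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        # every ordering passes through a stop; fall back to counting all
        # orderings with stop steps as nonsynonymous
        for order in permutations(positions):
            current = ca
            sd = nd = 0.0
            for pos in order:
                nxt = current[:pos] + cb[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS or _CODE[nxt] != _CODE.get(current, None):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def _jukes_cantor(p: float, kind: str) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"{kind} proportion {p:.3f} at or beyond the correctable ceiling 3/4"
        )
    return -0.75 * float(np.log(1 - 4.0 * p / 3.0))


def dnds_nei_gojobori(seq_a: str, seq_b: str) -> DnDsResult:
    """Nei–Gojobori dN/dS for a gap-free codon-aligned sequence pair."""
    ca = _codons(seq_a, "seq_a")
    cb = _codons(seq_b, "seq_b")
    if len(ca) != len(cb):
        raise DnDsError(f"length mismatch: {len(ca)} vs {len(cb)} codons")
    s_a = sum(_syn_sites(c) for c in ca)
    s_b = sum(_syn_sites(c) for c in cb)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(ca) - S
    Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sd, nd = _pathway_diffs(x, y)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS, "synonymous") if Sd > 0 else 0.0
    dN = _jukes_cantor(pN, "nonsynonymous") if Nd > 0 else 0.0
    omega = dN / dS if dS > 0 else None
    return DnDsResult(dN=dN, dS=dS, omega=omega, N_sites=N, S_sites=S, Nd=Nd, Sd=Sd)


def read_codon_pairs(path) -> list[tuple[str, str, str]]:
    """Read paired coding sequences from FASTA.

    Records are paired by identifier prefix: ``NAME_1`` and ``NAME_2``
    (suffix after the last underscore) form the pair ``NAME``.
    """
    groups: dict[str, dict[str, str]] = {}
    for rec in _parse_fasta(str(path), "fasta"):
        if "_" not in rec.id:
            raise DnDsError(f"record id {rec.id!r} has no pairing suffix")
        name, suffix = rec.id.rsplit("_", 1)
        groups.setdefault(name, {})[suffix] = str(rec.seq)
    pairs = []
    for name in sorted(groups):
        seqs = groups[name]
        if len(seqs) != 2:
            raise DnDsError(f"pair {name!r} has {len(seqs)} members, expected 2")
        (sa, sb) = (seqs[k] for k in sorted(seqs))
        pairs.append((name, sa, sb))
    return pairs
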