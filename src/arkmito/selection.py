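"""Nei-Gojobori (1986) Ka/Ks estimation for codon alignments.

Approximate-counting method: synonymous/nonsynonymous site fractions are
read off the genetic code per codon (a single-nucleotide change that
creates a stop codon counts as nonsynonymous), multi-hit codon pairs are
averaged over all minimal mutational pathways with equal weights
(pathways through stop codons excluded, unless every pathway is blocked),
and proportions are corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p).

The ratio omega = Ka/Ks < 1 indicates purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import mannwhitneyu

from .orf_scan import INVERTEBRATE_MITO, GeneticCode

NT = "ACGT"

#: sentinel ratios
RATIO_UNDEFINED = float("nan")
RATIO_INFINITE = float("inf")


@dataclass
class CodonAlignment:
    gene_id: str
    pairs: list[tuple[str, str]]  # gap-free codon columns
    code: GeneticCode = INVERTEBRATE_MITO


@dataclass
class KaKsResult:
    gene_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float


class SaturationError(ValueError):
    """Raised when a proportion of differences reaches the JC limit (3/4)."""


def syn_site_fraction(codon: str, code: GeneticCode = INVERTEBRATE_MITO) -> float:
    """Number of synonymous sites in one codon (0..3).

    At each position, each of the 3 possible changes is synonymous iff the
    mutant codon encodes the same amino acid; changes to stop codons are
    nonsynonymous.
    """
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} in alignment")
    aa = code.aa(codon)
    s = 0.0
    for pos in range(3):
        for nt in NT:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if not code.is_stop(mut) and code.aa(mut) == aa:
                s += 1.0 / 3.0
    return s


def pathway_differences(c1: str, c2: str, code: GeneticCode = INVERTEBRATE_MITO) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal mutational pathways.

    Pathways visiting a stop codon are discarded; if all are blocked the
    average falls back to every pathway.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        sd = sum(1.0 for a, b in steps if not code.is_stop(a) and not code.is_stop(b)
                 and code.aa(a) == code.aa(b))
        nd = len(steps) - sd
        paths.append((blocked, sd, nd))
    usable = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not usable:
        usable = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise SaturationError(f"proportion of differences {p:.3f} >= 3/4; distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for a gap-free codon alignment."""
    if not aln.pairs:
        raise ValueError("empty codon alignment")
    code = aln.code
    S = N = Sd = Nd = 0.0
    for c1, c2 in aln.pairs:
        s1 = syn_site_fraction(c1, code)
        s2 = syn_site_fraction(c2, code)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = pathway_differences(c1, c2, code)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    if Ks == 0.0:
        ratio = RATIO_UNDEFINED if Ka == 0.0 else RATIO_INFINITE
    else:
        ratio = Ka / Ks
    return KaKsResult(aln.gene_id, S, N, Sd, Nd, ps, pn, Ks, Ka, ratio)


# ---------------------------------------------------------------------------
# Codon-aware alignment


def _strip_terminal_stop(cds: str, code: GeneticCode) -> str:
    if len(cds) >= 3 and code.is_stop(cds[-3:]):
        return cds[:-3]
    return cds


def _translate_nostop(cds: str, code: GeneticCode) -> str:
    return "".join(code.aa(cds[i : i + 3]) for i in range(0, len(cds) - len(cds) % 3, 3))


def codon_align(
    protein_alignment: tuple[str, str],
    cdsA: str,
    cdsB: str,
    gene_id: str = "",
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonAlignment:
    """Back-translate a gapped protein alignment onto the two CDSs.

    Protein gaps expand to codon gaps; gapped columns are dropped so the
    result is a list of paired codons.  Terminal stop codons are stripped
    from the CDSs first.
    """
    rowA, rowB = protein_alignment
    if len(rowA) != len(rowB):
        raise ValueError("alignment rows differ in length")
    a = _strip_terminal_stop(cdsA.upper(), code)
    b = _strip_terminal_stop(cdsB.upper(), code)
    a = a[: len(a) - len(a) % 3]
    b = b[: len(b) - len(b) % 3]
    pa = _translate_nostop(a, code)
    pb = _translate_nostop(b, code)
    if rowA.replace("-", "") != pa:
        raise ValueError(f"{gene_id}: protein row A does not match translation of cdsA")
    if rowB.replace("-", "") != pb:
        raise ValueError(f"{gene_id}: protein row B does not match translation of cdsB")
    pairs = []
    ia = ib = 0
    for colA, colB in zip(rowA, rowB):
        ca = cb = None
        if colA != "-":
            ca = a[3 * ia : 3 * ia + 3]
            ia += 1
        if colB != "-":
            cb = b[3 * ib : 3 * ib + 3]
            ib += 1
        if ca is not None and cb is not None:
            pairs.append((ca, cb))
    return CodonAlignment(gene_id, pairs, code)


def align_cds_pair(cdsA: str, cdsB: str, gene_id: str = "", code: GeneticCode = INVERTEBRATE_MITO) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    a = _strip_terminal_stop(cdsA.upper(), code)
    b = _strip_terminal_stop(cdsB.upper(), code)
    pa = _translate_nostop(a[: len(a) - len(a) % 3], code)
    pb = _translate_nostop(b[: len(b) - len(b) % 3], code)
    if "*" in pa or "*" in pb:
        raise ValueError(f"{gene_id}: internal stop codon in CDS")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aln = aligner.align(pa.replace("*", "X"), pb.replace("*", "X"))[0]
    return codon_align((str(aln[0]), str(aln[1])), cdsA, cdsB, gene_id, code)


def batch_kaks(
    gene_pairs: list[tuple[str, str, str, str]],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[list[tuple[str, str, KaKsResult]], dict]:
    """Ka/Ks for a batch of orthologous CDS pairs.

    ``gene_pairs``: (gene_id, group, cdsA, cdsB) with group in {PCG, ORF}.
    Returns per-gene results plus group summary (mean Ka, Ks, ratio per
    group and a two-sided Mann-Whitney U P value for the ratio difference).
    """
    rows = []
    for gene_id, group, cdsA, cdsB in gene_pairs:
        res = ng86(align_cds_pair(cdsA, cdsB, gene_id, code))
        rows.append((gene_id, group, res))
    summary: dict = {}
    ratios = {"PCG": [], "ORF": []}
    for _, group, res in rows:
        if group in ratios and math.isfinite(res.ratio):
            ratios[group].append(res.ratio)
    for group, vals in ratios.items():
        summary[f"mean_ratio_{group}"] = float(np.mean(vals)) if vals else float("nan")
        summary[f"mean_ka_{group}"] = float(
            np.mean([r.Ka for _, g, r in rows if g == group])
        ) if any(g == group for _, g, _ in rows) else float("nan")
        summary[f"mean_ks_{group}"] = float(
            np.mean([r.Ks for _, g, r in rows if g == group])
        ) if any(g == group for _, g, _ in rows) else float("nan")
    if ratios["PCG"] and ratios["ORF"]:
        stat, p = mannwhitneyu(ratios["ORF"], ratios["PCG"], alternative="two-sided")
        summary["mannwhitney_U"] = float(stat)
        summary["mannwhitney_p"] = float(p)
    return rows, summary


def write_kaks_table(rows: list[tuple[str, str, KaKsResult]], path) -> None:
    cols = ["gene", "group", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gene_id, group, r in rows:
            fh.write(
                f"{gene_id}\t{group}\t{r.S:.4f}\t{r.N:.4f}\t{r.Sd:.4f}\t{r.Nd:.4f}"
                f"\t{r.Ka:.6f}\t{r.Ks:.6f}\t{r.ratio:.6f}\n"
            )
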