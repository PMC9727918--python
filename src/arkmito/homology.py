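"""Pairwise protein alignment, duplication families and presence screening.

Replaces database BLAST with explicit affine-gap dynamic programming
(BLOSUM62, gap open 11 / extend 1, BLAST cost convention: a gap of length
k costs 11 + k).  Percent identity is computed over all aligned columns
including gap columns, so values are directly comparable across pairs.
Presence of a query ORF in another mitogenome is called from the best
local hit against (i) proteins of ORFs found in that genome's URs and
(ii) six-frame translations of the UR sequence, classified by
identity and query-coverage thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, reverse_complement
from .orf_scan import INVERTEBRATE_MITO, find_orfs
from .ur_analysis import extract_urs, label_shared_urs


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    mode: str  # global | local
    score: float
    identity_pct: float
    query_coverage_pct: float
    subject_coverage_pct: float
    n_columns: int


@dataclass
class PresenceCall:
    query_orf: str
    genome_id: str
    status: str  # complete | partial | absent
    best_hit: AlignmentResult | None


@dataclass
class OrfFamily:
    members: list[str]
    representative: str
    identities: dict  # (a, b) -> identity_pct


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST 11/1: gap of length k costs 11 + k
    a.open_gap_score = -12
    a.extend_gap_score = -1
    return a


def _sanitize(p: str) -> str:
    """Map residues outside the BLOSUM62 alphabet (and stops) to X."""
    alpha = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in alpha else "X" for c in p.upper())


def align_proteins(a: str, b: str, mode: str = "global", query_id: str = "a", subject_id: str = "b") -> AlignmentResult:
    """Affine-gap pairwise alignment of two proteins.

    Identity denominator counts every aligned column, gaps included.
    Coverage is the aligned fraction of each input sequence (always 100
    in global mode).
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    sa, sb = _sanitize(a), _sanitize(b)
    aligner = _aligner(mode)
    aln = aligner.align(sa, sb)[0]  # deterministic first traceback
    qa, qb = str(aln[0]), str(aln[1])
    ncols = len(qa)
    matches = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    q_aligned = sum(1 for x in qa if x != "-")
    s_aligned = sum(1 for y in qb if y != "-")
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        mode=mode,
        score=float(aln.score),
        identity_pct=100.0 * matches / ncols if ncols else 0.0,
        query_coverage_pct=100.0 * q_aligned / len(sa),
        subject_coverage_pct=100.0 * s_aligned / len(sb),
        n_columns=ncols,
    )


def six_frame_peptides(seq: str, code=INVERTEBRATE_MITO, min_aa: int = 10) -> list[str]:
    """Stop-free peptides from all six reading frames of a DNA sequence."""
    peptides = []
    for s in (seq, reverse_complement(seq)):
        for frame in range(3):
            aas = [code.aa(s[i : i + 3]) for i in range(frame, len(s) - 2, 3)]
            for pep in "".join(aas).split("*"):
                if len(pep) >= min_aa:
                    peptides.append(pep)
    return peptides


def screen_genome(
    query_orfs: dict[str, str],
    rec: GenomeRecord,
    min_ident: float = 30.0,
    complete_cov: float = 90.0,
    partial_cov: float = 30.0,
    min_nt: int = 75,
    min_score: float = 50.0,
) -> list[PresenceCall]:
    """Classify each query protein as complete/partial/absent in ``rec``.

    Subjects are the proteins of all ORFs found in the genome's URs plus
    six-frame UR peptides (catching unannotated or frame-broken copies).
    ``min_score`` is a raw-alignment-score floor standing in for a BLAST
    E-value cutoff: identity/coverage percentages alone cannot separate a
    short chance similarity from a real one, while a homologous stretch of
    even ten conserved residues clears 50 BLOSUM62 score units easily.
    """
    urs = label_shared_urs(extract_urs(rec), rec)
    subjects: dict[str, str] = {}
    for ur in urs:
        ur_seq = (
            rec.sequence[ur.start :] + rec.sequence[: ur.end]
            if ur.wraps
            else rec.sequence[ur.start : ur.end]
        )
        if len(ur_seq) < min_nt:
            continue
        for orf in find_orfs(ur_seq, min_nt=min_nt, genome_id=rec.id, region_label=ur.label,
                             region_start=ur.start):
            if orf.protein:
                subjects[f"orf:{orf.name}"] = orf.protein
        for k, pep in enumerate(six_frame_peptides(ur_seq)):
            subjects[f"6f:{ur.start}.{k}"] = pep
    calls = []
    for qid in sorted(query_orfs):
        qprot = query_orfs[qid]
        best: AlignmentResult | None = None
        for sid in sorted(subjects):
            res = align_proteins(qprot, subjects[sid], mode="local", query_id=qid, subject_id=sid)
            if best is None or res.score > best.score:
                best = res
        status = "absent"
        if best is not None and best.score >= min_score and best.identity_pct >= min_ident:
            if best.query_coverage_pct >= complete_cov:
                status = "complete"
            elif best.query_coverage_pct >= partial_cov:
                status = "partial"
        calls.append(PresenceCall(qid, rec.id, status, best))
    return calls


def presence_matrix(
    queries: dict[str, str],
    recs: list[GenomeRecord],
    **thresholds,
) -> dict[str, dict[str, str]]:
    """rows = genomes, columns = queries, cells in {complete, partial, absent}."""
    matrix: dict[str, dict[str, str]] = {}
    for rec in recs:
        calls = screen_genome(queries, rec, **thresholds)
        matrix[rec.id] = {c.query_orf: c.status for c in calls}
    return matrix


def write_presence_matrix(matrix: dict[str, dict[str, str]], path) -> None:
    queries = sorted({q for row in matrix.values() for q in row})
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(queries) + "\n")
        for gid in sorted(matrix):
            fh.write(gid + "\t" + "\t".join(matrix[gid].get(q, "absent") for q in queries) + "\n")


def cluster_families(
    orfs: dict[str, str] | None = None,
    family_min_ident: float = 28.0,
    identities: dict | None = None,
) -> list[OrfFamily]:
    """Single-linkage clustering of ORFs at a protein-identity threshold.

    Either supply protein sequences (``orfs``; pairwise global identities
    are computed) or a precomputed symmetric ``identities`` map
    ``(a, b) -> pct``.  Families are connected components of the graph
    linking pairs with identity >= threshold, ordered by smallest member.
    """
    if identities is None:
        if not orfs:
            raise ValueError("need orfs or identities")
        ids = sorted(orfs)
        identities = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                identities[(a, b)] = align_proteins(orfs[a], orfs[b]).identity_pct
    else:
        ids = sorted({x for pair in identities for x in pair} | set(orfs or {}))
    parent = {x: x for x in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), ident in identities.items():
        if ident >= family_min_ident:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)
    fams = []
    for root in sorted(groups):
        members = sorted(groups[root])
        sub = {
            (a, b): v
            for (a, b), v in identities.items()
            if a in members and b in members
        }
        fams.append(OrfFamily(members=members, representative=members[0], identities=sub))
    return fams
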