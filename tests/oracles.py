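"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration, deliberately
avoiding the package's own code paths.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


# ---------------------------------------------------------------------------
# ORF enumeration (six-frame, table 5 via Biopython translation)

STOPS = {"TAA", "TAG"}


def orf_enumerate(seq, min_nt=75, starts=("ATG", "ATA", "ATT", "GTG"),
                  strands=("+",), allow_open_end=True):
    """All ORFs: per frame, first permitted start after each stop up to the
    next stop; open frames at the 3' end reported with their trailing
    T/TA/none remainder.  Returns (strand, start, end, stop_kind) tuples in
    forward-strand coordinates."""
    calls = []
    n = len(seq)
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            open_at = None
            for i in codon_starts:
                c = s[i : i + 3]
                if "N" in c:
                    continue
                if c in STOPS:
                    if open_at is not None and i + 3 - open_at >= min_nt:
                        calls.append(_map(strand, open_at, i + 3, c, n))
                    open_at = None
                elif open_at is None and c in starts:
                    open_at = i
            if open_at is not None and allow_open_end:
                tail_start = codon_starts[-1] + 3 if codon_starts else frame
                tail = s[tail_start:]
                if tail in ("T", "TA"):
                    end = n
                    kind = tail
                else:
                    end = tail_start
                    kind = "none"
                if end - open_at >= min_nt:
                    calls.append(_map(strand, open_at, end, kind, n))
    return sorted(calls)


def _map(strand, a, b, kind, n):
    if strand == "+":
        return (strand, a, b, kind)
    return (strand, n - b, n - a, kind)


# ---------------------------------------------------------------------------
# tandem repeats


def smallest_period_naive(u: str) -> int:
    for p in range(1, len(u) + 1):
        if len(u) % p == 0 and u == u[:p] * (len(u) // p):
            return p
    return len(u)


def repeat_enumerate(seq, max_period=300, min_copies=2.0, min_total_len=6):
    """All maximal primitive exact tandem runs by direct (pos, period) scan."""
    n = len(seq)
    out = []
    for p in range(1, min(max_period, n // 2) + 1):
        for i in range(n - p):
            if i > 0 and i - 1 + p < n and seq[i - 1] == seq[i - 1 + p]:
                continue
            j = i
            while j + p < n and seq[j] == seq[j + p]:
                j += 1
            total = (j - i) + p
            copies = total / p
            if copies < min_copies or total < min_total_len:
                continue
            if smallest_period_naive(seq[i : i + p]) != p:
                continue
            out.append((i, p, seq[i : i + p], copies, total))
    return sorted(out)


# ---------------------------------------------------------------------------
# affine-gap global alignment score (Gotoh), BLOSUM62 with gap cost 11 + k


def gotoh_global_score(a: str, b: str, matrix, open_cost=12, extend_cost=1) -> float:
    NEG = -1e9
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (moving down a)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, lb + 1):
        Y[0, j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - extend_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - extend_cost)
    return float(max(M[la, lb], X[la, lb], Y[la, lb]))


# ---------------------------------------------------------------------------
# NG86 by direct enumeration with Biopython translation (table 5)


def _aa5(codon: str) -> str:
    return str(Seq(codon).translate(table=5))


def ng86_enumerate(pairs):
    """(S, N, Sd, Nd) for a list of codon pairs; everything by enumeration."""
    S = Sd = Nd = 0.0
    for c1, c2 in pairs:
        for c in (c1, c2):
            syn = 0.0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == c[pos]:
                        continue
                    m = c[:pos] + nt + c[pos + 1 :]
                    if _aa5(m) != "*" and _aa5(m) == _aa5(c):
                        syn += 1 / 3
            S += syn / 2
        diff = [k for k in range(3) if c1[k] != c2[k]]
        if diff:
            results = []
            for order in permutations(diff):
                cur = c1
                sd = nd = 0
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if _aa5(nxt) == "*":
                        blocked = True
                        nd += 1
                    elif _aa5(cur) == "*":
                        nd += 1
                    elif _aa5(nxt) == _aa5(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                results.append((blocked, sd, nd))
            ok = [(sd, nd) for blocked, sd, nd in results if not blocked]
            if not ok:
                ok = [(sd, nd) for _, sd, nd in results]
            Sd += sum(r[0] for r in ok) / len(ok)
            Nd += sum(r[1] for r in ok) / len(ok)
    N = 3 * len(pairs) - S
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# BM ancestral states by explicit re-rooting + covariance GLS


def bm_gls_states(newick: str, tip_values: dict) -> dict:
    """Estimate every internal node state by re-rooting and explicit GLS."""
    import dendropy

    base = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = []
    for i, nd in enumerate(nd for nd in base.preorder_node_iter() if not nd.is_leaf()):
        if nd.label is None:
            nd.label = f"node{i}"
        labels.append(nd.label)
    rewritten = base.as_string(schema="newick", suppress_rooting=True)

    states = {}
    for label in labels:
        t = dendropy.Tree.get(data=rewritten, schema="newick",
                              preserve_underscores=True,
                              suppress_internal_node_taxa=False)
        node = next(nd for nd in t.preorder_node_iter()
                    if (nd.label == label) or (nd.taxon and nd.taxon.label == label))
        if node is not t.seed_node:
            t.reroot_at_node(node)
        tips = [lf for lf in t.leaf_node_iter()]
        depth = {t.seed_node: 0.0}
        for nd in t.preorder_node_iter():
            if nd is not t.seed_node:
                depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        n = len(tips)
        C = np.zeros((n, n))
        anc = {}
        for i, a in enumerate(tips):
            path = set()
            nd = a
            while nd is not None:
                path.add(nd)
                nd = nd.parent_node
            anc[i] = path
        for i in range(n):
            for j in range(i, n):
                nd = tips[j]
                while nd not in anc[i]:
                    nd = nd.parent_node
                C[i, j] = C[j, i] = depth[nd]
        x = np.array([tip_values[lf.taxon.label] for lf in tips])
        Cinv = np.linalg.inv(C)
        one = np.ones(n)
        states[label] = float(one @ Cinv @ x / (one @ Cinv @ one))
    return states
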