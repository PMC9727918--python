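"""Unassigned-region (UR) delimitation, statistics and tandem-repeat census.

URs are the circular complement of the union of all annotated features.
Ark-shell (Arcidae) mitogenomes carry two large shared URs: UR1 between
cox2 (or its duplicate cox2-b) and nad6, and UR2 between nad2 and cox1;
everything else between genes is plain intergenic DNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .genome_io import Feature, GenomeRecord

UR1_FLANKS = (("cox2", "cox2-b"), ("nad6",))
UR2_FLANKS = (("nad2",), ("cox1",))


@dataclass
class UnassignedRegion:
    genome_id: str
    start: int
    end: int
    wraps: bool
    length_nt: int
    label: str = "intergenic"  # UR1 | UR2 | intergenic
    upstream_gene: str = ""
    downstream_gene: str = ""


@dataclass
class URReportRow:
    genome_id: str
    genome_size: int
    total_ur_len: int
    ur_pct: float
    ur1_len: int
    ur1_pct: float
    ur2_len: int
    ur2_pct: float
    intergenic_len: int


@dataclass
class TandemRepeat:
    start: int
    period: int
    unit: str
    copies: float
    total_len: int


def round_pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to 2 decimals (the table convention)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _covered_intervals(rec: GenomeRecord) -> list[tuple[int, int]]:
    """Union of all feature spans, unwrapped onto the linear axis [0, n)."""
    n = rec.length_nt
    raw: list[tuple[int, int]] = []
    for f in rec.features:
        if f.wraps:
            raw.append((f.start, n))
            raw.append((0, f.end))
        else:
            raw.append((f.start, f.end))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def extract_urs(rec: GenomeRecord, min_len: int = 1) -> list[UnassignedRegion]:
    """Complement of the feature union on the circle.

    Gaps adjacent across the origin merge into one wrapping UR; gaps
    shorter than ``min_len`` are dropped.
    """
    n = rec.length_nt
    if n == 0:
        raise ValueError("zero-length genome")
    cov = _covered_intervals(rec)
    if not cov:
        return [UnassignedRegion(rec.id, 0, 0, rec.circular, n)]
    gaps: list[tuple[int, int, bool]] = []  # (start, end, wraps)
    for (a1, b1), (a2, b2) in zip(cov, cov[1:]):
        if a2 > b1:
            gaps.append((b1, a2, False))
    head = cov[0][0]  # gap before first feature
    tail = n - cov[-1][1]  # gap after last feature
    if rec.circular:
        if head + tail > 0:
            if tail > 0 and head > 0:
                gaps.append((cov[-1][1], head, True))
            elif tail > 0:
                gaps.append((cov[-1][1], n, False))
            else:
                gaps.append((0, head, False))
    else:
        if head > 0:
            gaps.insert(0, (0, head, False))
        if tail > 0:
            gaps.append((cov[-1][1], n, False))
    urs = []
    for start, end, wraps in gaps:
        length = (end - start) % n if wraps else end - start
        if length >= min_len:
            urs.append(UnassignedRegion(rec.id, start, end % n if wraps else end, wraps, length))
    urs.sort(key=lambda u: u.start)
    return urs


def _flanking_genes(ur: UnassignedRegion, rec: GenomeRecord) -> tuple[str, str]:
    """Names of the nearest features ending at / starting from the UR ends."""
    n = rec.length_nt

    def dist_before(f: Feature) -> int:
        end = f.end if not f.wraps else f.end
        return (ur.start - end) % n

    def dist_after(f: Feature) -> int:
        return (f.start - ur.end) % n

    if not rec.features:
        return "", ""
    up = min(rec.features, key=dist_before)
    down = min(rec.features, key=dist_after)
    return up.name, down.name


def label_shared_urs(
    urs: list[UnassignedRegion],
    rec: GenomeRecord,
    ur1_flanks=UR1_FLANKS,
    ur2_flanks=UR2_FLANKS,
) -> list[UnassignedRegion]:
    """Assign UR1/UR2 labels by flanking-gene identity.

    UR1 lies between cox2 (or cox2-b where the duplicate is present) and
    nad6; UR2 between nad2 and cox1.  Wrapping URs qualify.  Everything
    unmatched stays ``intergenic``.
    """
    for ur in urs:
        ur.upstream_gene, ur.downstream_gene = _flanking_genes(ur, rec)
        ur.label = "intergenic"
        if ur.upstream_gene in ur1_flanks[0] and ur.downstream_gene in ur1_flanks[1]:
            ur.label = "UR1"
        elif ur.upstream_gene in ur2_flanks[0] and ur.downstream_gene in ur2_flanks[1]:
            ur.label = "UR2"
    return urs


def ur_report(recs: list[GenomeRecord], min_len: int = 1) -> list[URReportRow]:
    rows = []
    for rec in recs:
        urs = label_shared_urs(extract_urs(rec, min_len), rec)
        total = sum(u.length_nt for u in urs)
        ur1 = sum(u.length_nt for u in urs if u.label == "UR1")
        ur2 = sum(u.length_nt for u in urs if u.label == "UR2")
        rows.append(
            URReportRow(
                genome_id=rec.id,
                genome_size=rec.length_nt,
                total_ur_len=total,
                ur_pct=round_pct(total, rec.length_nt),
                ur1_len=ur1,
                ur1_pct=round_pct(ur1, rec.length_nt),
                ur2_len=ur2,
                ur2_pct=round_pct(ur2, rec.length_nt),
                intergenic_len=total - ur1 - ur2,
            )
        )
    return rows


def write_ur_report(rows: list[URReportRow], path) -> None:
    cols = [
        "genome_id",
        "genome_size",
        "total_ur_len",
        "ur_pct",
        "ur1_len",
        "ur1_pct",
        "ur2_len",
        "ur2_pct",
        "intergenic_len",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Exact tandem repeats


def _smallest_period(unit: str) -> int:
    """Smallest p such that unit is (unit[:p])^k; via the KMP failure border."""
    m = len(unit)
    fail = [0] * (m + 1)
    k = 0
    for i in range(1, m):
        while k and unit[i] != unit[k]:
            k = fail[k]
        if unit[i] == unit[k]:
            k += 1
        fail[i + 1] = k
    p = m - fail[m]
    return p if m % p == 0 else m


def find_tandem_repeats(
    seq: str,
    max_period: int = 300,
    min_copies: float = 2.0,
    min_total_len: int = 6,
) -> list[TandemRepeat]:
    """Maximal exact tandem runs, each reported once at its primitive period.

    A run of period ``p`` starting at ``i`` is maximal when it cannot be
    extended left (``seq[i-1] != seq[i-1+p]``) and is reported only if its
    unit ``seq[i:i+p]`` is primitive.  Trailing fractional copies count.
    Deterministic left-to-right, short-period-first order.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    out: list[TandemRepeat] = []
    for p in range(1, min(max_period, n // 2) + 1):
        # match[i] = length of the longest run of positions j >= i with
        # seq[j] == seq[j+p]; computed right-to-left in O(n).
        match = [0] * (n + 1)
        for i in range(n - p - 1, -1, -1):
            match[i] = match[i + 1] + 1 if seq[i] == seq[i + p] else 0
        for i in range(n - p):
            if i > 0 and seq[i - 1] == seq[i - 1 + p]:
                continue  # not a left-maximal start
            total = p + match[i]
            copies = total / p
            if copies < min_copies or total < min_total_len:
                continue
            if _smallest_period(seq[i : i + p]) != p:
                continue  # non-primitive unit: reported at the smaller period
            out.append(TandemRepeat(i, p, seq[i : i + p], copies, total))
    out.sort(key=lambda r: (r.start, r.period))
    return out


def repeat_statistics(
    recs: list[GenomeRecord],
    max_period: int = 300,
    min_copies: float = 2.0,
    min_total_len: int = 6,
) -> list[dict]:
    """Per-genome tandem-repeat totals restricted to UR spans."""
    rows = []
    for rec in recs:
        urs = label_shared_urs(extract_urs(rec), rec)
        count = 0
        total_len = 0
        total_ur = sum(u.length_nt for u in urs)
        for ur in urs:
            if ur.wraps:
                ur_seq = rec.sequence[ur.start :] + rec.sequence[: ur.end]
            else:
                ur_seq = rec.sequence[ur.start : ur.end]
            reps = find_tandem_repeats(ur_seq, max_period, min_copies, min_total_len)
            count += len(reps)
            total_len += sum(r.total_len for r in reps)
        rows.append(
            {
                "genome_id": rec.id,
                "repeat_count": count,
                "repeat_total_len": total_len,
                "pct_of_urs": round_pct(total_len, total_ur),
            }
        )
    return rows


def write_repeats_bed(repeats: list[TandemRepeat], chrom: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tunit\tperiod\tcopies\n")
        for r in repeats:
            fh.write(
                f"{chrom}\t{r.start}\t{r.start + r.total_len}\t{r.unit}\t{r.period}\t{r.copies:.2f}\n"
            )
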