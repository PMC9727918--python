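"""Seeded generators for synthetic ark-shell-like mitogenomes.

Produces circular single-strand-coded genomes with the Arcidae layout:
two coding blocks, a large UR1 between the cox2/cox2-b pair and nad6, a
large UR2 between nad2 and cox1 (optionally wrapping the origin), planted
ORFs (some paralogous at controlled amino-acid identity, some ending on a
truncated stop), exact tandem repeats, codon pairs diverged with exact
synonymous/nonsynonymous substitution counts, multinomial read counts
from a true TPM vector, and BM-evolved trait values on a tree.  Every
planted element is recorded in a :class:`GroundTruth` so each analysis
stage can be scored exactly.

UR background sequence is AT-rich and explicitly sanitized: any chance
ORF or tandem run above the reporting thresholds that falls outside a
planted span is broken by a point substitution, so recovery tests are
sharp (found set == planted set at the default thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome_io import Feature, GenomeRecord, rotate_genome
from .orf_scan import INVERTEBRATE_MITO, find_orfs
from .ur_analysis import find_tandem_repeats
from .homology import align_proteins

# Fig-5-like shared gene order on the + strand: coding block A, UR1,
# coding block B, UR2, back to cox1.  Lengths in nt (stop codon included).
DEFAULT_GENE_TEMPLATE = [
    ("cox1", "CDS", 1536),
    ("cox3", "CDS", 780),
    ("atp6", "CDS", 708),
    ("cob", "CDS", 1140),
    ("cox2", "CDS", 666),
    ("cox2-b", "CDS", 1179),
    ("UR1", None, None),
    ("nad6", "CDS", 504),
    ("nad5", "CDS", 1713),
    ("nad1", "CDS", 927),
    ("nad4L", "CDS", 297),
    ("rrnS", "rRNA", 843),
    ("rrnL", "rRNA", 1296),
    ("nad3", "CDS", 354),
    ("nad4", "CDS", 1329),
    ("nad2", "CDS", 963),
    ("UR2", None, None),
]

# Planted novel ORFs: (name, nt_len incl. stop, start codon, stop codon).
# "T" marks a truncated stop: the ORF must then sit at the 3' end of its UR.
DEFAULT_ORF_PLAN = {
    "UR1": [
        ("ORF87", 1983, "ATG", "TAG"),
        ("ORF40", 831, "ATG", "TAG"),
        ("ORF104", 513, "ATA", "TAG"),
        ("ORF8", 636, "ATA", "TAA"),
        ("ORF10", 585, "ATG", "TAG"),
        ("ORF11", 603, "ATA", "TAA"),
    ],
    "UR2": [
        ("ORF127", 1872, "ATG", "TAG"),
        ("ORF5", 762, "ATA", "TAA"),
        ("ORF86", 582, "ATA", "TAG"),
        ("ORF103", 246, "ATG", "TAA"),
        ("ORF21", 238, "ATG", "T"),
    ],
}

# Paralog pairs mirrored from the duplication structure of the study system.
DEFAULT_DUPLICATION_PLAN = [
    ("ORF87", "ORF127", 67.0),
    ("ORF8", "ORF11", 47.0),
]

# (region, period nt, copies) exact tandem repeats.
DEFAULT_REPEAT_PLAN = [
    ("UR1", 12, 8.0),
    ("UR1", 27, 5.0),
    ("UR2", 5, 6.0),
    ("UR2", 64, 4.0),
]

SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in INVERTEBRATE_MITO.stops
)

# Thresholds above which chance background hits are removed.
SANITIZE_MIN_ORF_NT = 75
SANITIZE_MIN_REPEAT_LEN = 12
SANITIZE_MAX_PERIOD = 150


@dataclass
class SynthConfig:
    seed: int = 0
    gene_template: list = field(default_factory=lambda: [list(x) for x in DEFAULT_GENE_TEMPLATE])
    ur1_len: int = 9938
    ur2_len: int = 16045
    orf_plan: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ORF_PLAN.items()})
    duplication_plan: list = field(default_factory=lambda: list(DEFAULT_DUPLICATION_PLAN))
    repeat_plan: list = field(default_factory=lambda: list(DEFAULT_REPEAT_PLAN))
    origin_in_ur2: bool = True
    at_fraction: float = 0.68  # Arcidae mitogenomes are AT-rich
    genome_id: str = "SYN000001"
    species: str = "Synthetica arcidae"

    @classmethod
    def small(cls, seed: int = 0) -> "SynthConfig":
        """Reduced-scale preset for fast tests: shorter genes and URs."""
        template = [
            ["cox1", "CDS", 450], ["cox3", "CDS", 300], ["atp6", "CDS", 240],
            ["cob", "CDS", 330], ["cox2", "CDS", 300], ["cox2-b", "CDS", 360],
            ["UR1", None, None],
            ["nad6", "CDS", 270], ["nad5", "CDS", 480], ["nad1", "CDS", 300],
            ["nad4L", "CDS", 210], ["rrnS", "rRNA", 250], ["rrnL", "rRNA", 350],
            ["nad3", "CDS", 240], ["nad4", "CDS", 420], ["nad2", "CDS", 330],
            ["UR2", None, None],
        ]
        return cls(
            seed=seed,
            gene_template=template,
            ur1_len=1800,
            ur2_len=2600,
            orf_plan={
                "UR1": [("ORF87", 399, "ATG", "TAG"), ("ORF8", 240, "ATA", "TAA")],
                "UR2": [("ORF127", 381, "ATG", "TAG"), ("ORF21", 142, "ATG", "T")],
            },
            duplication_plan=[("ORF87", "ORF127", 67.0), ],
            repeat_plan=[("UR1", 7, 4.0), ("UR2", 13, 3.0)],
            genome_id="SYNSMALL1",
        )


@dataclass
class GroundTruth:
    genome_id: str
    genes: dict = field(default_factory=dict)  # name -> [start, end)
    orfs: dict = field(default_factory=dict)  # name -> {start, end, nt_len, stop, protein, cds}
    repeats: list = field(default_factory=list)  # {region, start, period, copies, total_len}
    families: list = field(default_factory=list)  # lists of ORF names
    ur_spans: dict = field(default_factory=dict)  # label -> [start, end, wraps]
    presence_plan: dict = field(default_factory=dict)
    divergence: dict = field(default_factory=dict)  # gene -> {n_syn, n_nonsyn}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# sequence building blocks


def _random_sense_codons(rng: np.random.Generator, n: int, at: float) -> list[str]:
    """Sense codons sampled with an AT-rich nucleotide bias."""
    w = np.array([
        np.prod([(at / 2 if c in "AT" else (1 - at) / 2) for c in codon])
        for codon in SENSE_CODONS
    ])
    w /= w.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n, p=w)
    return [SENSE_CODONS[i] for i in idx]


def random_cds(rng: np.random.Generator, nt_len: int, start: str = "ATG",
               stop: str = "TAA", at: float = 0.68) -> str:
    """A coding sequence of ``nt_len`` nt: start codon + sense codons + stop.

    A truncated stop ("T"/"TA") yields a non-multiple-of-3 length, as in
    mitochondrial genes completed by polyadenylation.
    """
    body_nt = nt_len - 3 - len(stop)
    if body_nt < 0 or body_nt % 3:
        raise ValueError(f"infeasible CDS length {nt_len} with stop {stop!r}")
    codons = _random_sense_codons(rng, body_nt // 3, at)
    return start + "".join(codons) + stop


def random_background(rng: np.random.Generator, n: int, at: float = 0.68) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def protein_of(cds: str) -> str:
    code = INVERTEBRATE_MITO
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if code.is_stop(codon):
            break
        aas.append(code.aa(codon))
    return "".join(aas)


_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _AA_TO_CODONS.setdefault(INVERTEBRATE_MITO.aa(_c), []).append(_c)


def back_translate(rng: np.random.Generator, protein: str, start: str,
                   stop: str) -> str:
    """Random synonymous back-translation; first residue uses the start codon."""
    codons = []
    for i, aa in enumerate(protein):
        if i == 0:
            codons.append(start)
        else:
            codons.append(_AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))])
    return "".join(codons) + stop


# ---------------------------------------------------------------------------
# targeted mutation


AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def mutate_to_identity(protein: str, target_pct: float, seed: int,
                       tol: float = 2.0, max_iter: int = 10000) -> str:
    """Randomly substitute residues until global identity hits the target.

    Identity is measured with the package's own global aligner (gap columns
    in the denominator), so the realized value is directly comparable to
    screening output.  Raises when the target is infeasible.
    """
    if not 0 < target_pct <= 100:
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    cur = list(protein)
    ident = 100.0
    if target_pct >= 100.0 - tol:
        return protein
    for _ in range(max_iter):
        if abs(ident - target_pct) <= tol:
            return "".join(cur)
        if ident > target_pct:
            pos = int(rng.integers(len(cur)))
            old = cur[pos]
            new = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
            if new == old:
                continue
            cur[pos] = new
            ident = align_proteins(protein, "".join(cur)).identity_pct
            if ident < target_pct - tol:  # overshot: revert
                cur[pos] = old
                ident = align_proteins(protein, "".join(cur)).identity_pct
        else:
            # undershot (should be rare thanks to revert): restore a residue
            diffs = [i for i, (a, b) in enumerate(zip(protein, cur)) if a != b]
            if not diffs:
                break
            pos = int(rng.choice(diffs))
            cur[pos] = protein[pos]
            ident = align_proteins(protein, "".join(cur)).identity_pct
    raise ValueError(f"could not reach identity {target_pct}% within tolerance")


def _codon_changes(codon: str, synonymous: bool) -> list[str]:
    code = INVERTEBRATE_MITO
    out = []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_stop(mut):
                continue
            if (code.aa(mut) == code.aa(codon)) == synonymous:
                out.append(mut)
    return out


def diverge_cds(cds: str, n_syn: int, n_nonsyn: int, seed: int) -> tuple[str, dict]:
    """Apply exactly ``n_syn``/``n_nonsyn`` single-nt substitutions.

    At most one substitution per codon (keeps the counts unambiguous for
    pathway counting); the start codon and the stop are left untouched.
    Returns the mutated CDS and the realized per-codon bookkeeping.
    """
    rng = np.random.default_rng(seed)
    stop_len = len(cds) % 3 or 3
    n_codons = (len(cds) - stop_len) // 3 if len(cds) % 3 else len(cds) // 3 - 1
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    editable = list(range(1, n_codons))  # spare the start codon
    rng.shuffle(editable)
    applied = {"syn": [], "nonsyn": []}
    want = [(True, n_syn), (False, n_nonsyn)]
    for synonymous, n_want in want:
        done = 0
        i = 0
        while done < n_want and i < len(editable):
            ci = editable[i]
            i += 1
            options = _codon_changes(codons[ci], synonymous)
            if not options:
                continue
            codons[ci] = options[int(rng.integers(len(options)))]
            editable.remove(ci)
            i -= 1
            applied["syn" if synonymous else "nonsyn"].append(ci)
            done += 1
        if done < n_want:
            raise ValueError(
                f"only {done}/{n_want} {'synonymous' if synonymous else 'nonsynonymous'} "
                "changes feasible"
            )
    tail = cds[3 * n_codons :]
    return "".join(codons) + tail, applied


# ---------------------------------------------------------------------------
# UR assembly and sanitation


def _break_orfs(seq: list[str], protected, rng, skip_orfs: set,
                placed_stops: list) -> bool:
    s = "".join(seq)
    changed = False
    for orf in find_orfs(s, min_nt=SANITIZE_MIN_ORF_NT):
        if (orf.start, orf.end) in skip_orfs:
            continue
        # candidate in-frame codons whose 3 nt avoid every protected span
        # and every stop already written for another frame (an ORF partially
        # overlapping a planted element can still be broken in its free part)
        candidates = [
            orf.start + 3 * ci
            for ci in range(1, (orf.end - orf.start) // 3 - 1)
            if not any(_overlaps(range(orf.start + 3 * ci, orf.start + 3 * ci + 3), p)
                       for p in protected + placed_stops)
        ]
        if not candidates:
            skip_orfs.add((orf.start, orf.end))  # fully inside planted spans
            continue
        removable = [p for p in candidates if p + 3 - orf.start < SANITIZE_MIN_ORF_NT]
        if removable:
            # random choice avoids ping-pong between overlapping frames
            pos = removable[int(rng.integers(len(removable)))]
        else:
            # the head of the ORF is locked inside a planted span: cap it at
            # the earliest free codon and accept the residual short ORF
            pos = min(candidates)
            skip_orfs.add((orf.start, pos + 3))
        seq[pos : pos + 3] = list("TAA")
        placed_stops.append(range(pos, pos + 3))
        changed = True
    return changed


def _break_repeats(seq: list[str], protected_reps, orf_spans, rng, skip) -> bool:
    """Break unplanted tandem runs; inside planted ORFs only synonymous
    codon edits are allowed (the ORF and its protein must survive)."""
    s = "".join(seq)
    changed = False
    for rep in find_tandem_repeats(s, max_period=SANITIZE_MAX_PERIOD,
                                   min_total_len=SANITIZE_MIN_REPEAT_LEN):
        key = (rep.start, rep.period)
        span = range(rep.start, rep.start + rep.total_len)
        if key in skip or any(_overlaps(span, p) for p in protected_reps):
            continue
        hit_orfs = [o for o in orf_spans if _overlaps(span, range(o[0], o[1]))]
        guards = [range(o[0] - 3, o[1]) for o in orf_spans]
        free = [pos for pos in span
                if not any(pos in g for g in guards)
                and not any(pos in p for p in protected_reps)]
        if free:
            # prefer a position in the second copy so the run shrinks fast;
            # random replacement avoids deterministic toggling cycles
            pos = next((p for p in free if p >= rep.start + rep.period), free[-1])
            alts = [n for n in "ACGT" if n != seq[pos]]
            seq[pos] = alts[int(rng.integers(3))]
            changed = True
        elif _synonymous_break(seq, span, hit_orfs):
            changed = True
        else:
            skip.add(key)  # no mutable site available; leave the run
    return changed


def _synonymous_break(seq: list[str], span: range, orf_spans) -> bool:
    code = INVERTEBRATE_MITO
    for pos in span:
        for s0, e0 in orf_spans:
            if not (s0 <= pos < e0):
                continue
            ci = (pos - s0) // 3
            if ci == 0:  # never touch the start codon
                continue
            cs = s0 + 3 * ci
            if cs + 3 > e0:
                continue
            codon = "".join(seq[cs : cs + 3])
            off = pos - cs
            for nt in "ACGT":
                if nt == codon[off]:
                    continue
                mut = codon[:off] + nt + codon[off + 1 :]
                if not code.is_stop(mut) and code.aa(mut) == code.aa(codon):
                    seq[pos] = nt
                    return True
    return False


def _overlaps(a: range, b: range) -> bool:
    return a.start < b.stop and b.start < a.stop


def build_ur(
    rng: np.random.Generator,
    length: int,
    orfs: list[tuple[str, str]],  # (name, cds) in placement order
    repeats: list[tuple[int, float]],  # (period, copies)
    at: float,
    terminal_truncated: str | None = None,  # name of ORF ending at the 3' UR edge
) -> tuple[str, dict, list[dict]]:
    """Assemble one UR: background + planted ORFs + planted tandem repeats.

    Each planted ORF is preceded by an in-frame TAA so the scanner's
    5'-most-start rule recovers exactly the planted interval.  Repeat run
    boundaries are broken on both sides so planted runs are maximal.
    Chance ORFs/repeats in the background are removed by point mutation.
    """
    elements: list[tuple[str, str]] = []  # (kind:name, seq)
    for name, cds in orfs:
        if name == terminal_truncated:
            continue
        elements.append((f"orf:{name}", "TAA" + cds))
    rep_specs = []
    for period, copies in repeats:
        unit = random_background(rng, period, at)
        while len(unit) > 1 and _primitive_period(unit) != period:
            unit = random_background(rng, period, at)
        total = int(round(period * copies))
        run = (unit * int(np.ceil(copies)))[:total]
        rep_specs.append((period, copies, unit, run))
        elements.append((f"rep:{period}:{copies}", run))
    tail = ""
    tail_name = None
    if terminal_truncated is not None:
        cds = dict(orfs)[terminal_truncated]
        tail = "TAA" + cds
        tail_name = terminal_truncated
    fixed = sum(len(s) for _, s in elements) + len(tail)
    n_gaps = len(elements) + 1
    bg_total = length - fixed
    if bg_total < n_gaps * 4:
        raise ValueError(
            f"planted content ({fixed} nt) overflows UR capacity ({length} nt)"
        )
    gap_sizes = [bg_total // n_gaps] * n_gaps
    gap_sizes[-1] += bg_total - sum(gap_sizes)
    parts: list[str] = []
    placements: dict = {}
    rep_placed: list[dict] = []
    pos = 0
    for i, (tag, s) in enumerate(elements):
        bg = random_background(rng, gap_sizes[i], at)
        parts.append(bg)
        pos += len(bg)
        if tag.startswith("orf:"):
            placements[tag[4:]] = (pos + 3, pos + len(s))  # skip the guard TAA
        else:
            _, period, copies = tag.split(":")
            rep_placed.append(
                {"start": pos, "period": int(period), "copies": float(copies),
                 "total_len": len(s)}
            )
        parts.append(s)
        pos += len(s)
    parts.append(random_background(rng, gap_sizes[-1], at))
    pos += gap_sizes[-1]
    if tail:
        placements[tail_name] = (pos + 3, pos + len(tail))
        parts.append(tail)
        pos += len(tail)
    seq = list("".join(parts))
    assert len(seq) == length, (len(seq), length)

    # force planted repeat runs to be maximal (boundaries mismatch)
    for rp in rep_placed:
        i, p, tot = rp["start"], rp["period"], rp["total_len"]
        if i > 0 and seq[i - 1] == seq[i - 1 + p]:
            seq[i - 1] = _different(seq[i - 1 + p])
        j = i + tot
        if j < length and seq[j] == seq[j - p]:
            seq[j] = _different(seq[j - p])

    orf_spans = [(s, e) for s, e in placements.values()]
    protected = [range(s - 3, e) for s, e in placements.values()]
    protected_reps = [range(r["start"] - 1, r["start"] + r["total_len"] + 1)
                      for r in rep_placed]
    skip: set = set()
    skip_orfs: set = set()
    placed_stops: list = []
    for _ in range(60):
        c1 = _break_orfs(seq, protected + protected_reps, rng, skip_orfs, placed_stops)
        c2 = _break_repeats(seq, protected_reps, orf_spans, rng, skip)
        if not (c1 or c2):
            break
    else:
        raise RuntimeError("background sanitation did not converge")
    return "".join(seq), placements, rep_placed


def _different(nt: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[nt]


def _primitive_period(unit: str) -> int:
    from .ur_analysis import _smallest_period

    return _smallest_period(unit)


# ---------------------------------------------------------------------------
# genome generation


def _orf_cds_set(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    """CDS per planted ORF, honouring the duplication plan."""
    dup_targets = {new: (src, ident) for src, new, ident in cfg.duplication_plan}
    specs = {name: (nt, start, stop) for region in cfg.orf_plan.values()
             for name, nt, start, stop in region}
    cds_map: dict[str, str] = {}

    def make(name: str) -> str:
        if name in cds_map:
            return cds_map[name]
        nt_len, start, stop = specs[name]
        if name in dup_targets:
            src, ident = dup_targets[name]
            src_prot = protein_of(make(src))
            n_aa = (nt_len - len(stop)) // 3  # residues incl. the start Met
            base = (src_prot * (n_aa // len(src_prot) + 1))[:n_aa]
            mutated = mutate_to_identity(base, ident, int(rng.integers(2**31)))
            cds_map[name] = back_translate(rng, mutated, start, stop)
        else:
            cds_map[name] = random_cds(rng, nt_len, start, stop, cfg.at_fraction)
        return cds_map[name]

    for name in specs:
        make(name)
    return cds_map


def gen_genome(cfg: SynthConfig) -> tuple[GenomeRecord, GroundTruth]:
    """Build one annotated circular mitogenome plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(genome_id=cfg.genome_id)
    orf_cds = _orf_cds_set(cfg, rng)

    ur_seqs: dict[str, tuple[str, dict, list]] = {}
    for label in ("UR1", "UR2"):
        plan = cfg.orf_plan.get(label, [])
        orfs = [(name, orf_cds[name]) for name, *_ in plan]
        truncated = next((name for name, _, _, stop in plan if stop in ("T", "TA")), None)
        reps = [(p, c) for region, p, c in cfg.repeat_plan if region == label]
        length = cfg.ur1_len if label == "UR1" else cfg.ur2_len
        ur_seqs[label] = build_ur(rng, length, orfs, reps, cfg.at_fraction, truncated)

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for name, kind, length in cfg.gene_template:
        if name in ("UR1", "UR2"):
            seq, placements, reps = ur_seqs[name]
            for oname, (s, e) in placements.items():
                cds = seq[s:e]  # as assembled (synonymous sanitation may edit)
                stop = next(st for n, _, _, st in
                            (cfg.orf_plan["UR1"] + cfg.orf_plan["UR2"]) if n == oname)
                truth.orfs[oname] = {
                    "start": pos + s, "end": pos + e, "nt_len": e - s,
                    "stop": stop, "region": name,
                    "protein": protein_of(cds), "cds": cds,
                }
            for r in reps:
                truth.repeats.append({"region": name, "start": pos + r["start"],
                                      "period": r["period"], "copies": r["copies"],
                                      "total_len": r["total_len"]})
            truth.ur_spans[name] = [pos, pos + len(seq), False]
            parts.append(seq)
            pos += len(seq)
        else:
            if kind == "CDS":
                seq = random_cds(rng, length, "ATG", "TAA", cfg.at_fraction)
            else:
                seq = random_background(rng, length, cfg.at_fraction)
            features.append(Feature(kind=kind, name=name, start=pos, end=pos + length))
            truth.genes[name] = [pos, pos + length]
            parts.append(seq)
            pos += length

    # duplication families (singletons omitted)
    fam: dict[str, set] = {}
    for src, new, _ in cfg.duplication_plan:
        root = next((k for k, v in fam.items() if src in v or new in v), src)
        fam.setdefault(root, set()).update({src, new})
    truth.families = [sorted(v) for v in fam.values()]

    rec = GenomeRecord(cfg.genome_id, cfg.species, "".join(parts), True, features)
    if cfg.origin_in_ur2:
        s, e, _ = truth.ur_spans["UR2"]
        k = (s + (e - s) * 2 // 3) % rec.length_nt
        rec = rotate_genome(rec, k)
        n = rec.length_nt
        for d in truth.orfs.values():
            d["start"] = (d["start"] - k) % n
            d["end"] = (d["end"] - k) % n or n
        for r in truth.repeats:
            r["start"] = (r["start"] - k) % n
        for g in truth.genes.values():
            g[0], g[1] = (g[0] - k) % n, ((g[1] - k) % n) or n
        for lab, (s0, e0, _) in truth.ur_spans.items():
            s1, e1 = (s0 - k) % n, (e0 - k) % n
            truth.ur_spans[lab] = [s1, e1, s1 > e1]
    rec.validate()
    return rec, truth


# ---------------------------------------------------------------------------
# cohort / pair generators


def gen_cohort(
    cfg: SynthConfig,
    n_genomes: int,
    presence_plan: dict[int, dict[str, str]],
    query_source: tuple[GenomeRecord, GroundTruth] | None = None,
) -> tuple[list[tuple[GenomeRecord, GroundTruth]], dict[str, str]]:
    """Genomes carrying designated queries as complete/partial/absent copies.

    ``presence_plan[i]`` maps query ORF name -> status for genome i.
    Complete = full CDS copy planted; partial = an internal ~40% fragment
    re-framed as a mini-ORF; absent = not planted.  Returns the cohort and
    the query protein set (from the reference genome).
    """
    if query_source is None:
        # queries must be mutually dissimilar or a planted copy of one would
        # also register its paralog; the reference genome therefore carries
        # independent ORFs (no duplication plan)
        ref_cfg = SynthConfig(**asdict(cfg))
        ref_cfg.duplication_plan = []
        query_source = gen_genome(ref_cfg)
    ref_rec, ref_truth = query_source
    queries = {name: d["protein"] for name, d in ref_truth.orfs.items()}
    cohort = []
    for i in range(n_genomes):
        plan = presence_plan.get(i, {})
        sub = SynthConfig(**asdict(cfg))
        sub.seed = cfg.seed + 1000 * (i + 1)
        sub.genome_id = f"{cfg.genome_id}.{i + 1}"
        sub.duplication_plan = []
        ur1_plan: list = []
        ur2_plan: list = []
        overrides: dict[str, str] = {}
        for qname, status in sorted(plan.items()):
            d = ref_truth.orfs[qname]
            cds, stop = d["cds"], d["stop"]
            if status == "complete":
                cds_use = cds if stop in ("TAA", "TAG") else cds[: len(cds) - len(stop)] + "TAA"
                spec = (qname, len(cds_use), cds_use[:3], cds_use[-3:])
            elif status == "partial":
                n_codons = len(d["protein"])
                k = max(10, int(0.4 * n_codons))
                lo = (n_codons - k) // 2
                cds_use = "ATG" + cds[3 * lo : 3 * (lo + k)] + "TAA"
                spec = (qname + "_frag", len(cds_use), "ATG", "TAA")
            else:
                continue
            overrides[spec[0]] = cds_use
            (ur1_plan if len(ur1_plan) <= len(ur2_plan) else ur2_plan).append(spec)
        sub.orf_plan = {"UR1": ur1_plan, "UR2": ur2_plan}
        rec, truth = _gen_genome_with_cds(sub, overrides)
        truth.presence_plan = dict(plan)
        cohort.append((rec, truth))
    return cohort, queries


def _gen_genome_with_cds(cfg: SynthConfig, cds_overrides: dict[str, str]):
    """gen_genome variant where specific planted ORF CDSs are given verbatim."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(genome_id=cfg.genome_id)
    orf_cds = {}
    for region in cfg.orf_plan.values():
        for name, nt_len, start, stop in region:
            if name in cds_overrides:
                orf_cds[name] = cds_overrides[name]
            else:
                orf_cds[name] = random_cds(rng, nt_len, start, stop, cfg.at_fraction)

    ur_seqs = {}
    for label in ("UR1", "UR2"):
        plan = cfg.orf_plan.get(label, [])
        orfs = [(name, orf_cds[name]) for name, *_ in plan]
        truncated = next((name for name, _, _, stop in plan if stop in ("T", "TA")), None)
        reps = [(p, c) for region, p, c in cfg.repeat_plan if region == label]
        length = cfg.ur1_len if label == "UR1" else cfg.ur2_len
        ur_seqs[label] = build_ur(rng, length, orfs, reps, cfg.at_fraction, truncated)

    parts, features, pos = [], [], 0
    for name, kind, length in cfg.gene_template:
        if name in ("UR1", "UR2"):
            seq, placements, reps = ur_seqs[name]
            for oname, (s, e) in placements.items():
                cds = seq[s:e]
                truth.orfs[oname] = {
                    "start": pos + s, "end": pos + e, "nt_len": e - s,
                    "stop": "", "region": name,
                    "protein": protein_of(cds), "cds": cds,
                }
            for r in reps:
                truth.repeats.append({"region": name, **r})
            truth.ur_spans[name] = [pos, pos + len(seq), False]
            parts.append(seq)
            pos += len(seq)
        else:
            seq = (random_cds(rng, length, "ATG", "TAA", cfg.at_fraction)
                   if kind == "CDS" else random_background(rng, length, cfg.at_fraction))
            features.append(Feature(kind=kind, name=name, start=pos, end=pos + length))
            truth.genes[name] = [pos, pos + length]
            parts.append(seq)
            pos += length
    rec = GenomeRecord(cfg.genome_id, cfg.species, "".join(parts), True, features)
    rec.validate()
    return rec, truth


# planted substitution counts per gene group, as fractions of codon count:
# chosen so the NG86 ratio lands near 0.1 for protein-coding genes and
# near 0.4 for ORFs (purifying selection in both, weaker in ORFs)
PCG_DIVERGENCE = (0.05, 0.013)
ORF_DIVERGENCE = (0.05, 0.051)


def gen_conspecific_pair(
    cfg: SynthConfig,
    pcg_rates: tuple[float, float] = PCG_DIVERGENCE,
    orf_rates: tuple[float, float] = ORF_DIVERGENCE,
) -> tuple[list[tuple[str, str, str, str]], GroundTruth]:
    """Two same-species genomes' ortholog CDS pairs with planted divergence.

    Returns ``(gene_id, group, cdsA, cdsB)`` tuples ready for batch Ka/Ks,
    plus the ground truth with per-gene planted substitution counts.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    rec, truth = gen_genome(cfg)
    pairs = []
    for name, kind, length in cfg.gene_template:
        if kind != "CDS" or name == "cox2-b":
            continue  # the cox2 duplicate is not part of the canonical PCG panel
        s, e = truth.genes[name]
        cds = (rec.sequence[s:e] if s < e else rec.sequence[s:] + rec.sequence[:e])
        n_codons = len(cds) // 3 - 1
        ns = max(1, round(pcg_rates[0] * n_codons))
        nn = max(1, round(pcg_rates[1] * n_codons))
        mutated, _ = diverge_cds(cds, ns, nn, int(rng.integers(2**31)))
        truth.divergence[name] = {"n_syn": ns, "n_nonsyn": nn, "group": "PCG"}
        pairs.append((name, "PCG", cds, mutated))
    for oname, d in truth.orfs.items():
        cds = d["cds"]
        if d["stop"] not in ("TAA", "TAG"):
            cds = cds[: len(cds) - len(d["stop"])]  # drop the truncated stop
        n_codons = len(cds) // 3 - 1
        ns = max(1, round(orf_rates[0] * n_codons))
        nn = max(1, round(orf_rates[1] * n_codons))
        mutated, _ = diverge_cds(cds, ns, nn, int(rng.integers(2**31)))
        truth.divergence[oname] = {"n_syn": ns, "n_nonsyn": nn, "group": "ORF"}
        pairs.append((oname, "ORF", cds, mutated))
    return pairs, truth


# ---------------------------------------------------------------------------
# expression + trees


def gen_counts(
    true_tpm: dict[str, float],
    lengths: dict[str, int],
    depth: int,
    n_samples: int,
    seed: int,
):
    """Multinomial read counts from a true TPM vector.

    Read probability of feature i is proportional to TPM_i * length_i
    (TPM is a per-transcript measure; reads scale with transcript length).
    """
    from .expression import CountsTable

    ids = sorted(true_tpm)
    tpm = np.array([true_tpm[i] for i in ids], dtype=float)
    lens = np.array([lengths[i] for i in ids], dtype=float)
    p = tpm * lens
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p, size=n_samples).T
    return CountsTable(ids, lens, counts, [f"S{k + 1}" for k in range(n_samples)])


def gen_balanced_tree(n_tips: int, branch_length: float = 1.0) -> str:
    """Newick for a balanced binary tree with uniform branch lengths."""
    def build(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{branch_length}"
        mid = len(labels) // 2
        return f"({build(labels[:mid])},{build(labels[mid:])}):{branch_length}"

    labels = [f"t{i}" for i in range(n_tips)]
    if n_tips == 1:
        return f"({labels[0]}:{branch_length});"
    mid = n_tips // 2
    return f"({build(labels[:mid])},{build(labels[mid:])});"
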