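"""ORF discovery under the invertebrate mitochondrial genetic code (table 5).

Table 5 reassigns TGA->Trp, AGA/AGG->Ser and uses ATA as Met; stop codons
are TAA and TAG only.  Mitochondrial genes frequently end on a truncated
stop (a terminal T or TA completed to TAA by polyadenylation), so the
scanner can report open frames that run into the 3' boundary of a region
with ``complete_stop=False`` and stop codon "T", "TA" or "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_io import reverse_complement

#: start codons actually observed in Arcidae protein-coding genes
DEFAULT_STARTS = ("ATG", "ATA", "ATT", "GTG")

#: large-ORF (LORF) length threshold in nt
LORF_THRESHOLD = 933


@dataclass(frozen=True)
class GeneticCode:
    """A codon table: forward map plus start/stop sets."""

    table_id: int = 5
    forward: dict = field(default_factory=dict)
    stops: frozenset = frozenset()
    starts: frozenset = frozenset()

    @classmethod
    def from_ncbi(cls, table_id: int = 5, starts=None) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            stops=frozenset(t.stop_codons),
            starts=frozenset(starts if starts is not None else t.start_codons),
        )

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; '*' for stop, 'X' when ambiguous (N)."""
        if codon in self.stops:
            return "*"
        return self.forward.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def is_start(self, codon: str) -> bool:
        return codon in self.starts


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5, starts=DEFAULT_STARTS)


@dataclass
class OrfRecord:
    genome_id: str
    region_label: str
    start: int
    end: int
    wraps: bool
    strand: str
    frame: int
    nt_len: int
    start_codon: str
    stop_codon: str  # TAA | TAG | T | TA | none
    complete_stop: bool
    protein: str
    is_lorf: bool

    @property
    def name(self) -> str:
        return f"{self.genome_id}|{self.region_label}|{self.start}-{self.end}"


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO, allow_incomplete_stop: bool = False) -> str:
    """Translate a coding sequence; stops at the first stop codon.

    A trailing 1-2 nt remainder is tolerated only with
    ``allow_incomplete_stop`` (truncated mitochondrial stop).  Codons
    containing N translate to X.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    rem = len(cds) % 3
    if rem and not allow_incomplete_stop:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds) - rem, 3):
        codon = cds[i : i + 3]
        if code.is_stop(codon):
            break
        aas.append(code.aa(codon))
    return "".join(aas)


def _scan_strand(
    seq: str,
    code: GeneticCode,
    min_nt: int,
    starts: tuple,
    allow_incomplete_stop_at_end: bool,
    lorf_threshold: int,
    genome_id: str,
    region_label: str,
    strand: str,
    region_start: int,
    region_len: int,
) -> list["OrfRecord"]:
    n = len(seq)
    out = []
    for frame in range(3):
        open_start = None  # position of 5'-most permitted start since last stop
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if "N" in codon:
                i += 3
                continue  # N codons are neither start nor stop
            if code.is_stop(codon):
                if open_start is not None:
                    nt_len = i + 3 - open_start
                    if nt_len >= min_nt:
                        out.append(
                            _make_orf(
                                seq, open_start, i + 3, frame, codon, True, code,
                                genome_id, region_label, strand, region_start,
                                region_len, lorf_threshold,
                            )
                        )
                    open_start = None
            elif open_start is None and codon in starts:
                open_start = i
            i += 3
        # frame runs into the 3' end with an open ORF
        if open_start is not None and allow_incomplete_stop_at_end:
            tail = seq[i:]  # 0-2 leftover nt in this frame
            partial = ""
            if tail and "TAA".startswith(tail):
                partial = tail
            nt_len = n - open_start if partial else i - open_start
            stop = partial if partial else "none"
            if nt_len >= min_nt:
                out.append(
                    _make_orf(
                        seq, open_start, open_start + nt_len, frame, stop, False, code,
                        genome_id, region_label, strand, region_start, region_len,
                        lorf_threshold,
                    )
                )
    return out


def _make_orf(
    seq, s, e, frame, stop, complete, code, genome_id, region_label,
    strand, region_start, region_len, lorf_threshold,
):
    stop_len = 3 if complete else (len(stop) if stop != "none" else 0)
    cds = seq[s : e - stop_len]
    protein = "".join(code.aa(cds[i : i + 3]) for i in range(0, len(cds), 3))
    nt_len = e - s
    if strand == "+":
        g_start, g_end = region_start + s, region_start + e
    else:
        # coordinates on the forward strand of the scanned region
        g_start, g_end = region_start + (region_len - e), region_start + (region_len - s)
    return OrfRecord(
        genome_id=genome_id,
        region_label=region_label,
        start=g_start,
        end=g_end,
        wraps=False,
        strand=strand,
        frame=frame,
        nt_len=nt_len,
        start_codon=seq[s : s + 3],
        stop_codon=stop,
        complete_stop=complete,
        protein=protein,
        is_lorf=nt_len >= lorf_threshold,
    )


def find_orfs(
    seq: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    min_nt: int = 75,
    starts: tuple = DEFAULT_STARTS,
    strands: tuple = ("+",),
    allow_incomplete_stop_at_end: bool = True,
    lorf_threshold: int = LORF_THRESHOLD,
    genome_id: str = "",
    region_label: str = "",
    region_start: int = 0,
) -> list[OrfRecord]:
    """Scan a region for ORFs >= ``min_nt`` nt.

    Per frame and strand, an ORF runs from the 5'-most permitted start codon
    after the previous stop to the next in-frame stop (stop included in
    ``nt_len``).  Frames reaching the region end without a stop are reported
    with a truncated stop ("T"/"TA") or "none".  Overlapping ORFs in
    different frames are all reported.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < min_nt:
        return []
    out = []
    for strand in strands:
        scan_seq = seq if strand == "+" else reverse_complement(seq)
        out.extend(
            _scan_strand(
                scan_seq, code, min_nt, tuple(starts), allow_incomplete_stop_at_end,
                lorf_threshold, genome_id, region_label, strand, region_start, len(seq),
            )
        )
    out.sort(key=lambda o: (o.start, o.frame, o.strand))
    return out


def orf_table(orfs: list[OrfRecord]) -> list[dict]:
    """Flat per-ORF rows (sorted by genome then coordinate)."""
    rows = []
    for o in sorted(orfs, key=lambda o: (o.genome_id, o.start)):
        codons = f"{o.start_codon}-{o.stop_codon if o.stop_codon != 'none' else ''}"
        rows.append(
            {
                "genome_id": o.genome_id,
                "region": o.region_label,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "nt_len": o.nt_len,
                "aa_len": len(o.protein),
                "codons": codons,
                "complete_stop": o.complete_stop,
                "is_lorf": o.is_lorf,
            }
        )
    return rows


def write_orf_table(orfs: list[OrfRecord], path) -> None:
    rows = orf_table(orfs)
    cols = ["genome_id", "region", "start", "end", "strand", "nt_len", "aa_len",
            "codons", "complete_stop", "is_lorf"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
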