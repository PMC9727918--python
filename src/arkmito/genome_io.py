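"""Annotated circular mitogenome I/O and wrap-aware coordinate arithmetic.

Internal coordinates are 0-based half-open.  A feature that runs across the
origin of a circular genome is stored as a single :class:`Feature` with
``wraps=True``: its span is ``[start, length_nt)`` followed by ``[0, end)``.
GenBank ``join(a..L,1..b)`` locations map onto this representation on read
and are written back as joins.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "ORF")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated span on a (possibly circular) genome.

    ``start``/``end`` are 0-based half-open; ``wraps=True`` means the span
    runs ``start -> origin -> end``.  ``codon_start`` follows the GenBank
    qualifier (1-based offset of the first complete codon).
    """

    kind: str
    name: str
    start: int
    end: int
    wraps: bool = False
    strand: str = "+"
    codon_start: int = 1
    notes: str = ""

    def span_length(self, genome_length: int) -> int:
        if self.wraps:
            return (self.end - self.start) % genome_length
        return self.end - self.start

    def positions(self, genome_length: int):
        """Yield every genome position covered, in 5'->3' order on +."""
        if self.wraps:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)
        else:
            yield from range(self.start, self.end)


@dataclass
class GenomeRecord:
    """A mitogenome: sequence plus ordered features."""

    id: str
    species: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length_nt
        if n == 0:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN residues {sorted(bad)}")
        for f in self.features:
            if not (0 <= f.start < n and 0 <= f.end <= n):
                raise ValueError(
                    f"{self.id}:{f.name}: interval [{f.start},{f.end}) outside [0,{n})"
                )
            if f.wraps and not self.circular:
                raise ValueError(f"{self.id}:{f.name}: wrapping feature on linear genome")
            if f.span_length(n) < 1:
                raise ValueError(f"{self.id}:{f.name}: empty span")

    def feature_by_name(self, name: str) -> Feature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def feature_sequence(rec: GenomeRecord, f: Feature) -> str:
    """Extract the 5'->3' nucleotide sequence of a feature.

    Wrapping spans concatenate ``[start, L)`` with ``[0, end)``; minus-strand
    features return the reverse complement.  ``codon_start`` trimming is NOT
    applied here.
    """
    n = rec.length_nt
    if not (0 <= f.start < n and 0 <= f.end <= n):
        raise ValueError(f"feature [{f.start},{f.end}) out of range for length {n}")
    if f.wraps:
        s = rec.sequence[f.start :] + rec.sequence[: f.end]
    else:
        if f.end <= f.start:
            raise ValueError(f"degenerate non-wrapping span [{f.start},{f.end})")
        s = rec.sequence[f.start : f.end]
    return reverse_complement(s) if f.strand == "-" else s


# ---------------------------------------------------------------------------
# GenBank


def _location_to_span(loc, length: int) -> tuple[int, int, bool, str]:
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
            # join(a..L,1..b): wraps the origin
            return int(parts[1].start), int(parts[0].end), True, strand
        # fall back: bounding span
        return int(parts[0].start), int(parts[-1].end), False, strand
    return int(loc.start), int(loc.end), False, strand


def _feature_from_seqfeature(sf: SeqFeature, length: int) -> Feature | None:
    kind = sf.type
    if kind not in FEATURE_KINDS:
        return None
    q = sf.qualifiers
    name = (q.get("gene") or q.get("product") or q.get("locus_tag") or [""])[0]
    start, end, wraps, strand = _location_to_span(sf.location, length)
    codon_start = int((q.get("codon_start") or ["1"])[0])
    notes = "; ".join(q.get("note", []))
    return Feature(kind, name, start, end, wraps, strand, codon_start, notes)


def read_genbank(path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into :class:`GenomeRecord` objects.

    Origin-spanning ``join`` locations become single wrapping features.
    """
    records = []
    for sr in SeqIO.parse(str(path), "genbank"):
        seq = str(sr.seq).upper()
        declared = sr.annotations.get("declared_length")
        topology = sr.annotations.get("topology", "linear")
        length = len(seq)
        if declared is not None and int(declared) != length:
            raise ValueError(f"{sr.id}: LOCUS length {declared} != sequence length {length}")
        feats = []
        for sf in sr.features:
            f = _feature_from_seqfeature(sf, length)
            if f is not None:
                feats.append(f)
        rec = GenomeRecord(
            id=sr.id,
            species=sr.annotations.get("organism", sr.description),
            sequence=seq,
            circular=(topology == "circular"),
            features=feats,
        )
        rec.validate()
        records.append(rec)
    if not records:
        raise ValueError(f"no GenBank records parsed from {path}")
    return records


def _span_to_location(f: Feature, length: int) -> SimpleLocation | CompoundLocation:
    strand = -1 if f.strand == "-" else 1
    if f.wraps:
        return CompoundLocation(
            [SimpleLocation(f.start, length, strand), SimpleLocation(0, f.end, strand)]
        )
    return SimpleLocation(f.start, f.end, strand)


def write_genbank(recs: list[GenomeRecord], path) -> None:
    out = []
    for rec in recs:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id[:16], description=rec.species)
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        sr.annotations["organism"] = rec.species
        for f in rec.features:
            quals = {"gene": [f.name]}
            if f.kind in ("CDS", "ORF"):
                quals["codon_start"] = [str(f.codon_start)]
            if f.notes:
                quals["note"] = [f.notes]
            sr.features.append(
                SeqFeature(_span_to_location(f, rec.length_nt), type=f.kind, qualifiers=quals)
            )
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {sr.id: str(sr.seq).upper() for sr in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (write-only; coordinates 1-based inclusive per the format)


def write_gff3(recs: list[GenomeRecord], path) -> None:
    """Write features as GFF3.  Wrapping features are emitted as two lines
    sharing an ``ID`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in recs:
            fh.write(f"##sequence-region {rec.id} 1 {rec.length_nt}\n")
            for i, f in enumerate(rec.features):
                fid = f"{rec.id}.{i}.{f.name or f.kind}"
                attrs = f"ID={fid};Name={f.name}"
                parts = (
                    [(f.start + 1, rec.length_nt), (1, f.end)]
                    if f.wraps
                    else [(f.start + 1, f.end)]
                )
                for a, b in parts:
                    fh.write(
                        "\t".join(
                            [rec.id, "arkmito", f.kind, str(a), str(b), ".", f.strand, ".", attrs]
                        )
                        + "\n"
                    )


def genbank_roundtrip_equal(a: GenomeRecord, b: GenomeRecord) -> bool:
    """True when two records agree on sequence and feature geometry."""
    if (a.id, a.sequence, a.circular) != (b.id, b.sequence, b.circular):
        return False
    if len(a.features) != len(b.features):
        return False
    for fa, fb in zip(a.features, b.features):
        if (fa.kind, fa.name, fa.start, fa.end, fa.wraps, fa.strand) != (
            fb.kind,
            fb.name,
            fb.start,
            fb.end,
            fb.wraps,
            fb.strand,
        ):
            return False
    return True


def rotate_genome(rec: GenomeRecord, k: int) -> GenomeRecord:
    """Rotate the circular origin by ``k`` positions (new origin = old k).

    Feature coordinates follow; features that come to straddle the new
    origin gain ``wraps=True``.  Used for rotation-invariance checks.
    """
    n = rec.length_nt
    k %= n
    seq = rec.sequence[k:] + rec.sequence[:k]
    feats = []
    for f in rec.features:
        start = (f.start - k) % n
        end = (f.end - k) % n
        span = f.span_length(n)
        wraps = start + span > n
        if end == 0 and not wraps:
            end = n
        feats.append(replace(f, start=start, end=end % n if wraps else end, wraps=wraps))
    return GenomeRecord(rec.id, rec.species, seq, rec.circular, feats)
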