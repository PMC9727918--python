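"""TPM quantification of mitochondrial gene and ORF expression.

Consumes a featureCounts-style table (columns ``Geneid``, ``Length``, one
count column per sample) and converts counts to transcripts per million:

    TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)

Effective length is the annotated feature length (gene-level counting, no
fragment-length correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountsTable:
    feature_ids: list[str]
    lengths: np.ndarray  # nt, positive
    counts: np.ndarray  # features x samples, non-negative ints
    sample_ids: list[str]

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(self.lengths <= 0):
            raise ValueError("feature lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class ExpressionRecord:
    feature_id: str
    group: str  # PCG | ORF
    tpm: dict = field(default_factory=dict)  # sample -> TPM
    log2_tpm: dict = field(default_factory=dict)  # sample -> log2(TPM+1)


def read_counts_tsv(path) -> CountsTable:
    """Read a featureCounts-like TSV (comment lines starting with # skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = [c for c in df.columns if c in
                 ("Geneid", "Chr", "Start", "End", "Strand", "Length")]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return CountsTable(
        feature_ids=df["Geneid"].astype(str).tolist(),
        lengths=df["Length"].to_numpy(),
        counts=df[sample_cols].to_numpy(),
        sample_ids=sample_cols,
    )


def compute_tpm(table: CountsTable, groups: dict[str, str] | None = None) -> list[ExpressionRecord]:
    """Length-normalized TPM per sample; each sample column sums to 1e6.

    ``groups`` maps feature id -> {PCG, ORF}; defaults to ORF for ids
    starting with "ORF" and PCG otherwise.
    """
    rate = table.counts / table.lengths[:, None]
    denom = rate.sum(axis=0)
    tpm = np.zeros_like(rate)
    for j, d in enumerate(denom):
        if d == 0:
            warnings.warn(f"sample {table.sample_ids[j]}: all counts zero; TPM set to 0")
        else:
            tpm[:, j] = 1e6 * rate[:, j] / d
    records = []
    for i, fid in enumerate(table.feature_ids):
        group = (groups or {}).get(fid) or ("ORF" if fid.upper().startswith("ORF") else "PCG")
        records.append(
            ExpressionRecord(
                feature_id=fid,
                group=group,
                tpm={s: float(tpm[i, j]) for j, s in enumerate(table.sample_ids)},
                log2_tpm={s: float(np.log2(tpm[i, j] + 1)) for j, s in enumerate(table.sample_ids)},
            )
        )
    return records


def expression_summary(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Per-feature mean log2(TPM+1) across samples, ranked; group medians attached.

    Ties in the ranking break by feature id.
    """
    rows = []
    for r in records:
        vals = list(r.log2_tpm.values())
        rows.append(
            {
                "feature_id": r.feature_id,
                "group": r.group,
                "mean_log2_tpm": float(np.mean(vals)) if vals else 0.0,
                "mean_tpm": float(np.mean(list(r.tpm.values()))) if r.tpm else 0.0,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["mean_log2_tpm", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    for g in ("PCG", "ORF"):
        sub = df[df.group == g]
        df.attrs[f"median_log2_tpm_{g}"] = float(sub.mean_log2_tpm.median()) if len(sub) else float("nan")
    return df


def write_expression_tsv(records: list[ExpressionRecord], path) -> None:
    samples = sorted({s for r in records for s in r.tpm})
    with open(path, "w") as fh:
        fh.write("feature_id\tgroup\t" + "\t".join(f"tpm_{s}" for s in samples)
                 + "\t" + "\t".join(f"log2_{s}" for s in samples) + "\n")
        for r in records:
            fh.write(
                r.feature_id + "\t" + r.group + "\t"
                + "\t".join(f"{r.tpm.get(s, 0.0):.4f}" for s in samples) + "\t"
                + "\t".join(f"{r.log2_tpm.get(s, 0.0):.4f}" for s in samples) + "\n"
            )
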