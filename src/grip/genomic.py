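"""From peaks, TSS annotations and motif hits to per-TG regression inputs.

Region conventions: all coordinates are BED-style 0-based half-open. A
peak overlapping the 500 bp window immediately upstream of a gene's
transcription start site (strand-aware) is that gene's promoter peak;
any other same-chromosome peak within 250 kb of the TSS on either side is
a distal candidate functional region. Candidate TFs for a target gene are
the TFs with at least one motif hit inside the gene's promoter or distal
regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from grip.core import RegulationProblem
from grip.ppi import DSDMatrix, distance_submatrix

PROMOTER_BP = 500
WINDOW_BP = 250_000


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene TSS record; ``tss`` is a 0-based coordinate."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass
class CandidateSet:
    """Candidate TFs and regions for one target gene."""

    tg: str
    promoter_regions: list[GenomicRegion]
    distal_regions: list[GenomicRegion]
    candidate_tfs: list[str]
    tf_to_regions: dict[str, list[GenomicRegion]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tg": self.tg,
            "promoter_regions": [asdict(r) for r in self.promoter_regions],
            "distal_regions": [asdict(r) for r in self.distal_regions],
            "candidate_tfs": list(self.candidate_tfs),
            "tf_to_regions": {t: [asdict(r) for r in rs]
                              for t, rs in self.tf_to_regions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CandidateSet":
        d = json.loads(Path(path).read_text())
        mk = lambda r: GenomicRegion(**r)
        return cls(tg=d["tg"],
                   promoter_regions=[mk(r) for r in d["promoter_regions"]],
                   distal_regions=[mk(r) for r in d["distal_regions"]],
                   candidate_tfs=list(d["candidate_tfs"]),
                   tf_to_regions={t: [mk(r) for r in rs]
                                  for t, rs in d["tf_to_regions"].items()})


def promoter_interval(gene: GeneAnnotation,
                      promoter_bp: int = PROMOTER_BP) -> GenomicRegion:
    """The strand-aware upstream promoter window as a half-open interval."""
    if promoter_bp <= 0:
        raise ValueError("promoter_bp must be > 0")
    if gene.strand == "+":
        start = max(0, gene.tss - promoter_bp)
        return GenomicRegion(gene.chrom, start, max(gene.tss, start + 1))
    # minus strand: upstream means larger coordinates, (tss, tss + 500]
    return GenomicRegion(gene.chrom, gene.tss + 1, gene.tss + 1 + promoter_bp)


def classify_peaks(peaks: Sequence[GenomicRegion], gene: GeneAnnotation,
                   promoter_bp: int = PROMOTER_BP,
                   window_bp: int = WINDOW_BP,
                   ) -> tuple[list[GenomicRegion], list[GenomicRegion]]:
    """Split peaks into promoter and distal sets for one gene.

    Promoter: any peak overlapping the ``promoter_bp`` window immediately
    upstream of the TSS (strand-aware). Distal: any other same-chromosome
    peak overlapping ``[tss - window_bp, tss + window_bp)``. Peaks outside
    both are dropped; promoter classification takes precedence, so the two
    returned lists partition the in-window peaks.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    prom_iv = promoter_interval(gene, promoter_bp)
    win = GenomicRegion(gene.chrom, max(0, gene.tss - window_bp),
                        gene.tss + window_bp if window_bp else gene.tss + 1)
    promoter, distal = [], []
    for p in peaks:
        if p.overlaps(prom_iv):
            promoter.append(p)
        elif p.overlaps(win):
            distal.append(p)
    return promoter, distal


def candidate_set(tg: GeneAnnotation, peaks: Sequence[GenomicRegion],
                  motif_hits: pd.DataFrame,
                  promoter_bp: int = PROMOTER_BP, window_bp: int = WINDOW_BP,
                  include_promoter_hits: bool = True) -> CandidateSet:
    """Assemble the candidate-TF set of a target gene from motif hits.

    ``motif_hits`` needs columns ``tf_id, chrom, start, end``. A TF becomes
    a candidate when at least one of its hits overlaps a promoter or distal
    peak of the gene (set ``include_promoter_hits=False`` to count distal
    hits only).
    """
    promoter, distal = classify_peaks(peaks, tg, promoter_bp, window_bp)
    windows = (promoter if include_promoter_hits else []) + distal
    tf_to_regions: dict[str, list[GenomicRegion]] = {}
    for row in motif_hits.itertuples(index=False):
        hit = GenomicRegion(str(row.chrom), int(row.start), int(row.end))
        tf = str(row.tf_id).strip().upper()
        for w in windows:
            if hit.overlaps(w):
                tf_to_regions.setdefault(tf, [])
                if w not in tf_to_regions[tf]:
                    tf_to_regions[tf].append(w)
    return CandidateSet(tg=tg.gene_id, promoter_regions=promoter,
                        distal_regions=distal,
                        candidate_tfs=sorted(tf_to_regions),
                        tf_to_regions=tf_to_regions)


def assemble_problem(tg: str, expr: pd.DataFrame, candidates: CandidateSet,
                     dsd: DSDMatrix, rho: float = 1.0, lam: float = 0.1,
                     k: int = 3, missing_policy: str = "drop",
                     ) -> tuple[RegulationProblem, list[str]]:
    """Build a RegulationProblem for one TG from an expression table.

    ``expr`` is cells x genes with gene symbols as columns. The TG column
    is centered into y; candidate-TF columns are column-standardized into
    X (zero-variance candidates are dropped with a warning). TFs absent
    from the expression table or from the DSD matrix follow
    ``missing_policy``; the returned list names every TF that was dropped.
    """
    tg = str(tg).strip().upper()
    cols = {str(c).strip().upper(): c for c in expr.columns}
    if tg not in cols:
        raise KeyError(f"target gene {tg!r} absent from expression table")

    dropped: list[str] = []
    tf_ids = []
    for tf in candidates.candidate_tfs:
        tf = str(tf).strip().upper()
        if tf == tg:
            continue
        if tf not in cols:
            if missing_policy == "error":
                raise KeyError(f"candidate TF {tf!r} absent from expression table")
            dropped.append(tf)
            continue
        tf_ids.append(tf)

    y = expr[cols[tg]].to_numpy(dtype=float)
    y = y - y.mean()
    X_cols, kept = [], []
    for tf in tf_ids:
        x = expr[cols[tf]].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0.0:
            warnings.warn(f"candidate TF {tf} has constant expression; dropped")
            dropped.append(tf)
            continue
        X_cols.append((x - x.mean()) / sd)
        kept.append(tf)
    if not kept:
        raise ValueError(f"no candidate TF retained for {tg}")

    S, s_kept, s_missing = distance_submatrix(dsd, kept, missing_policy)
    dropped.extend(m for m in s_missing if m not in s_kept)
    if missing_policy == "drop" and s_missing:
        idx = [kept.index(t) for t in s_kept]
        X_cols = [X_cols[i] for i in idx]
        kept = s_kept
    if not kept:
        raise ValueError(f"no candidate TF retained for {tg}")
    X = np.column_stack(X_cols)
    problem = RegulationProblem(y=y, X=X, tf_ids=kept, S=S, rho=rho, lam=lam,
                                k=min(int(k), len(kept)))
    return problem, dropped


# --- plain-text IO helpers -------------------------------------------------

def read_peaks_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED3+ (no header) into regions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [GenomicRegion(str(r[0]), int(r[1]), int(r[2]))
            for r in df.itertuples(index=False)]


def read_tss_table(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a headered TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        g = GeneAnnotation(str(r.gene_id).strip().upper(), str(r.chrom),
                           int(r.tss), str(r.strand))
        out[g.gene_id] = g
    return out


def read_motif_hits(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV with columns tf_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t")
    need = {"tf_id", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"motif-hit table must have columns {sorted(need)}")
    df["tf_id"] = df["tf_id"].astype(str).str.strip().str.upper()
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a headered cells x genes TSV (first column = cell id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
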