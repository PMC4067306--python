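"""Reading, validation and export of chromosome-ordered expression profiles.

Canonical input is a long-format TSV (UTF-8, ``#`` comments ignored) with
columns ``gene  chrom  pos  log_ratio  sample`` — one row per sample x gene.
Each (sample, chromosome) pair becomes one profile with genes ordered from
the p-arm to the q-arm by base-pair position (ties broken by gene id).
Rows whose log-ratio is missing or non-finite are dropped and counted, so
profiles of the same chromosome may differ in length across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROFILE_COLUMNS = ("gene", "chrom", "pos", "log_ratio", "sample")
CN_COLUMNS = ("gene", "chrom", "pos", "fold_change", "sample")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    position: int
    log_ratio: float


@dataclass
class ExpressionProfile:
    """One chromosome of one sample: the ordered emission sequence."""

    sample_id: str
    chromosome: str
    gene_ids: np.ndarray
    positions: np.ndarray
    log_ratios: np.ndarray

    def __post_init__(self):
        if len(self.gene_ids) == 0:
            raise ValueError("empty profile")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"duplicate gene ids in profile {self.sample_id}/{self.chromosome}")
        order = np.lexsort((self.gene_ids, self.positions))
        self.gene_ids = np.asarray(self.gene_ids)[order]
        self.positions = np.asarray(self.positions, dtype=np.int64)[order]
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)[order]
        if np.any(self.positions < 0):
            raise ValueError("negative chromosomal position")

    @property
    def T(self) -> int:
        return len(self.log_ratios)

    @property
    def genes(self) -> list[GeneRecord]:
        return [
            GeneRecord(g, self.chromosome, int(p), float(x))
            for g, p, x in zip(self.gene_ids, self.positions, self.log_ratios)
        ]


@dataclass
class ProfileSet:
    profiles: list[ExpressionProfile]
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("empty profile set")

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)


@dataclass
class CopyNumberTrack:
    """Per-gene copy-number fold changes (linear scale) for one profile."""

    sample_id: str
    chromosome: str
    gene_ids: np.ndarray
    positions: np.ndarray
    fold_change: np.ndarray

    def __post_init__(self):
        if np.any(self.fold_change <= 0):
            raise ValueError("fold changes must be positive on the linear scale")
        order = np.lexsort((self.gene_ids, self.positions))
        self.gene_ids = np.asarray(self.gene_ids)[order]
        self.positions = np.asarray(self.positions, dtype=np.int64)[order]
        self.fold_change = np.asarray(self.fold_change, dtype=float)[order]


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip",
        dtype={"gene": str, "chrom": str, "sample": str},
    )
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    unknown = set(df.columns) - set(required)
    missing = set(required) - set(df.columns)
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_profiles(path) -> ProfileSet:
    """Read a long-format profile TSV into one profile per (sample, chromosome).

    Non-finite log-ratios are dropped; the count is available in
    ``ProfileSet.report['dropped']``.
    """
    df = _read_tsv(path, PROFILE_COLUMNS)
    dup = df.duplicated(subset=["sample", "chrom", "gene"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate (sample, chrom, gene): ({row['sample']}, {row['chrom']}, {row['gene']})")
    values = pd.to_numeric(df["log_ratio"], errors="coerce")
    keep = np.isfinite(values)
    dropped = int((~keep).sum())
    df = df[keep].assign(log_ratio=values[keep])
    if df.shape[0] == 0:
        raise ValueError(f"{path}: all log-ratios missing or non-finite")
    profiles = [
        ExpressionProfile(
            sample_id=sample,
            chromosome=chrom,
            gene_ids=grp["gene"].to_numpy(),
            positions=grp["pos"].to_numpy(),
            log_ratios=grp["log_ratio"].to_numpy(),
        )
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=True)
    ]
    return ProfileSet(profiles=profiles, report={"dropped": dropped})


def read_copy_numbers(path, scale: str = "linear") -> list[CopyNumberTrack]:
    """Read copy-number tables keyed like profiles; values become linear folds."""
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    df = _read_tsv(path, CN_COLUMNS)
    values = pd.to_numeric(df["fold_change"], errors="raise").to_numpy(dtype=float)
    if scale == "log2":
        values = 2.0**values
    elif np.any(values <= 0):
        raise ValueError("linear fold changes must be > 0")
    df = df.assign(fold_change=values)
    return [
        CopyNumberTrack(
            sample_id=sample,
            chromosome=chrom,
            gene_ids=grp["gene"].to_numpy(),
            positions=grp["pos"].to_numpy(),
            fold_change=grp["fold_change"].to_numpy(),
        )
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=True)
    ]


def write_profiles(profiles: ProfileSet, path) -> None:
    """Write profiles back to the canonical long-format TSV."""
    frames = [
        pd.DataFrame(
            {
                "gene": p.gene_ids,
                "chrom": p.chromosome,
                "pos": p.positions,
                "log_ratio": p.log_ratios,
                "sample": p.sample_id,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_posteriors(profile_posteriors, path, bed_path=None) -> None:
    """Write per-gene posteriors and decoded states as TSV (optionally BED).

    ``profile_posteriors`` is an iterable of (ExpressionProfile,
    PosteriorMatrix) pairs.  The BED output merges runs of consecutive genes
    decoded to the same state into 0-based half-open intervals.
    """
    from .inference import decode

    rows = []
    bed_rows = []
    states: tuple[str, ...] | None = None
    for profile, post in profile_posteriors:
        if post.gamma.shape[0] != profile.T:
            raise ValueError(
                f"posterior rows ({post.gamma.shape[0]}) do not match profile length ({profile.T})"
            )
        states = post.states
        labels = decode(post)
        for i in range(profile.T):
            rows.append(
                [
                    profile.gene_ids[i],
                    profile.chromosome,
                    int(profile.positions[i]),
                    profile.sample_id,
                    float(profile.log_ratios[i]),
                    *[float(x) for x in post.gamma[i]],
                    labels[i],
                ]
            )
        if bed_path is not None:
            start = 0
            for i in range(1, profile.T + 1):
                if i == profile.T or labels[i] != labels[start]:
                    bed_rows.append(
                        [
                            profile.chromosome,
                            int(profile.positions[start]),
                            int(profile.positions[i - 1]) + 1,
                            f"{profile.sample_id}:{labels[start]}",
                            0,
                            ".",
                        ]
                    )
                    start = i
    state_cols = [f"P({s})" for s in (states or ("=", "-", "+"))]
    header = ["gene", "chrom", "pos", "sample", "log_ratio", *state_cols, "decoded_state"]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        pd.DataFrame(bed_rows).to_csv(bed_path, sep="\t", index=False, header=False)
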