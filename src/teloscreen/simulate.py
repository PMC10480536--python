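"""Synthetic inputs with exactly known ground truth.

Everything the pipeline consumes can be generated here: FASTQ read sets
with a planted fraction of motif-bearing reads, cohorts of such samples
with a manifest and a true-ratio sidecar, qPCR Ct tables with known group
effects, and per-nucleus foci coordinate tables with a planted colocalized
fraction. All generators are fully deterministic under a fixed seed.

Background reads are rejection-sampled until motif-free on both strands,
so the planted count is the exact ground truth for the screen (a random
36-mer hit in a 50-base read has probability ~2*15/4^36 per read — not
zero, hence the explicit check).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .screen import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed stream: independent samples can be
    generated in any order (or in parallel) and still reproduce."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters for one simulated read set.

    planting_mode "exact_count" plants exactly floor(planted_fraction *
    n_reads) motif reads, making the screened ratio an exact, not
    statistical, quantity; "bernoulli" plants each read independently.
    strand_mix is the fraction of planted reads carrying the
    reverse-complement (C-strand) motif.
    """

    n_reads: int = 10_000
    read_length: int = 50
    planted_fraction: float = 0.01
    planting_mode: str = "exact_count"
    repeat_unit: str = "TTAGGG"
    copies: int = 6
    strand_mix: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise SimConfigError("n_reads must be positive")
        if self.read_length < 1:
            raise SimConfigError("read_length must be positive")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise SimConfigError("planted_fraction must be in [0, 1]")
        if self.planting_mode not in ("exact_count", "bernoulli"):
            raise SimConfigError(f"unknown planting_mode {self.planting_mode!r}")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise SimConfigError("strand_mix must be in [0, 1]")
        if not self.repeat_unit or any(c not in "ACGT" for c in self.repeat_unit):
            raise SimConfigError("repeat_unit must be nonempty uppercase ACGT")
        if self.copies < 1:
            raise SimConfigError("copies must be positive")
        motif_len = len(self.repeat_unit) * self.copies
        if self.planted_fraction > 0 and self.read_length < motif_len:
            raise SimConfigError(
                f"read_length {self.read_length} cannot hold the "
                f"{motif_len}-base motif"
            )

    @property
    def motif(self) -> str:
        return self.repeat_unit * self.copies


@dataclass(frozen=True)
class ReadSimSummary:
    n_reads: int
    n_planted: int


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    block = _BASES[codes].tobytes()
    return [block[i * length : (i + 1) * length].decode("ascii") for i in range(n)]


def _motif_free(seq: str, motif: str, motif_rc: str) -> bool:
    return motif not in seq and motif_rc not in seq


def generate_reads(config: ReadSimConfig, output: str | Path | IO[str]) -> ReadSimSummary:
    """Write a simulated FASTQ read set; returns the exact planted count.

    Planted reads carry the full motif at a uniformly chosen valid offset
    with random flanking bases; a strand_mix fraction carries the reverse
    complement instead. Background reads are uniform random bases,
    resampled until motif-free on both strands. Planted reads are mixed
    uniformly through the file. Quality lines are constant 'I' (the screen
    never reads qualities). Output may be a path (gzip if it ends in .gz)
    or an open text handle.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    motif = config.motif
    motif_rc = reverse_complement(motif)

    if config.planted_fraction == 0.0:
        planted = np.zeros(n, dtype=bool)
    elif config.planting_mode == "exact_count":
        k = math.floor(config.planted_fraction * n)
        planted = np.zeros(n, dtype=bool)
        planted[rng.permutation(n)[:k]] = True
    else:
        planted = rng.random(n) < config.planted_fraction

    seqs = _random_sequences(rng, n, config.read_length)
    max_offset = config.read_length - len(motif)
    for i in range(n):
        if planted[i]:
            use_rc = rng.random() < config.strand_mix
            ins = motif_rc if use_rc else motif
            off = int(rng.integers(0, max_offset + 1))
            s = seqs[i]
            seqs[i] = s[:off] + ins + s[off + len(motif):]
        else:
            while not _motif_free(seqs[i], motif, motif_rc):
                seqs[i] = _random_sequences(rng, 1, config.read_length)[0]

    qual = "I" * config.read_length
    records = "".join(
        f"@read_{i:07d}\n{seqs[i]}\n+\n{qual}\n" for i in range(n)
    )
    if hasattr(output, "write"):
        output.write(records)
    else:
        path = Path(output)
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                fh.write(records)
        else:
            path.write_text(records)
    return ReadSimSummary(n_reads=n, n_planted=int(planted.sum()))


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSimConfig:
    """A screen cohort: n_targets proteins with replicate read sets at a
    shared background repeat-read ratio, plus one or more telomere-
    associated-protein candidates ("tap_targets") at elevated ratios.

    Declared target names are the tap_targets keys (sorted) followed by
    generated filler names T01, T02, ...; elevated ratios must exceed
    background_ratio.
    """

    n_targets: int = 20
    replicates_per_target: int = 3
    background_ratio: float = 0.002
    tap_targets: dict[str, float] = field(default_factory=lambda: {"TAP1": 0.02})
    reads_per_sample: int = 10_000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.replicates_per_target < 1:
            raise SimConfigError("n_targets and replicates_per_target must be positive")
        if len(self.tap_targets) > self.n_targets:
            raise SimConfigError("more tap_targets than targets")
        if not 0.0 <= self.background_ratio <= 1.0:
            raise SimConfigError("background_ratio must be in [0, 1]")
        for name, ratio in self.tap_targets.items():
            if ratio <= self.background_ratio:
                raise SimConfigError(
                    f"tap target {name!r} ratio {ratio} must exceed background "
                    f"{self.background_ratio}"
                )

    def target_names(self) -> list[str]:
        names = sorted(self.tap_targets)
        i = 1
        while len(names) < self.n_targets:
            cand = f"T{i:02d}"
            if cand not in self.tap_targets:
                names.append(cand)
            i += 1
        return names


def generate_cohort(
    config: CohortSimConfig, output_dir: str | Path
) -> pd.DataFrame:
    """Generate per-sample FASTQ files, a manifest, and a true-ratio sidecar.

    Writes ``manifest.tsv`` (sample_id, target, path — paths relative to
    output_dir), ``truth.tsv`` (sample_id, true_ratio), and
    ``reads/<sample_id>.fastq``. Reads are planted in exact_count mode so
    each sample's true ratio is floor(r * n) / n exactly. Returns the
    manifest as a DataFrame.
    """
    out = Path(output_dir)
    reads_dir = out / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    truth = []
    sample_index = 0
    for target in config.target_names():
        ratio = config.tap_targets.get(target, config.background_ratio)
        for rep in range(1, config.replicates_per_target + 1):
            sample_id = f"{target}_rep{rep}"
            rel_path = f"reads/{sample_id}.fastq"
            rc = ReadSimConfig(
                n_reads=config.reads_per_sample,
                read_length=config.read_length,
                planted_fraction=ratio,
                planting_mode="exact_count",
                seed=_child_seed(config.seed, sample_index),
            )
            summary = generate_reads(rc, out / rel_path)
            rows.append({"sample_id": sample_id, "target": target, "path": rel_path})
            truth.append(
                {
                    "sample_id": sample_id,
                    "true_ratio": summary.n_planted / summary.n_reads,
                }
            )
            sample_index += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_ct_table(
    n_per_group: int,
    groups: dict[str, float],
    noise_sd: float = 0.0,
    base_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with known group effects.

    ``groups`` maps group name to a deltaCt offset: each sample draws
    ct_alb = base_ct + N(0, noise_sd) and ct_tel = ct_alb + offset +
    N(0, noise_sd), so the noise-free T/S of a group is exactly
    2^(-offset) (a negative offset means longer telomeres).
    """
    if not groups:
        raise SimConfigError("groups must be nonempty")
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be nonnegative")
    if n_per_group < 1:
        raise SimConfigError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:  # insertion order: deterministic
        offset = groups[group]
        for i in range(n_per_group):
            ct_alb = base_ct + rng.normal(0.0, noise_sd)
            ct_tel = ct_alb + offset + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:03d}",
                    "group": group,
                    "ct_tel": ct_tel,
                    "ct_alb": ct_alb,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# foci


@dataclass(frozen=True)
class FociSimConfig:
    """Per-nucleus 2D foci with a planted colocalized fraction.

    Colocalized foci share an anchor point drawn uniformly over the square
    field; each channel's focus sits at anchor + N(0, jitter_sd) per axis.
    Non-colocalized foci are uniform over the field. foci_per_channel maps
    each channel to a fixed per-nucleus count or to ("poisson", mean).
    """

    n_nuclei: int = 50
    field_size: float = 100.0
    foci_per_channel: dict[str, int | tuple[str, float]] = field(
        default_factory=lambda: {"MARKER": 10, "TEL": 10}
    )
    colocalized_fraction: float = 0.4
    jitter_sd: float = 0.0
    channels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        chans = tuple(self.channels) if self.channels else tuple(self.foci_per_channel)
        object.__setattr__(self, "channels", chans)
        if not 2 <= len(self.channels) <= 3:
            raise SimConfigError("need 2 or 3 channels")
        if set(self.channels) != set(self.foci_per_channel):
            raise SimConfigError("channels must match foci_per_channel keys")
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise SimConfigError("colocalized_fraction must be in [0, 1]")
        if self.jitter_sd < 0:
            raise SimConfigError("jitter_sd must be nonnegative")
        if self.field_size <= 0:
            raise SimConfigError("field_size must be positive")
        if self.n_nuclei < 1:
            raise SimConfigError("n_nuclei must be positive")


def _draw_count(rng: np.random.Generator, spec: int | tuple[str, float]) -> int:
    if isinstance(spec, tuple):
        dist, param = spec
        if dist != "poisson":
            raise SimConfigError(f"unknown count distribution {dist!r}")
        return int(rng.poisson(param))
    return int(spec)


def generate_foci(config: FociSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate foci coordinates; returns (foci table, ground truth).

    The foci table has columns nucleus_id, channel, x, y; the truth table
    has nucleus_id, n_coloc_true and per-channel counts. Per nucleus,
    floor(colocalized_fraction * min channel count) anchors produce one
    focus per channel.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.field_size
    rows = []
    truth = []
    for nid in range(1, config.n_nuclei + 1):
        nucleus_id = f"nuc{nid:04d}"
        counts = {
            ch: _draw_count(rng, config.foci_per_channel[ch]) for ch in config.channels
        }
        n_coloc = math.floor(config.colocalized_fraction * min(counts.values()))
        anchors = rng.uniform(0.0, fs, size=(n_coloc, 2))
        for ch in config.channels:
            pts = anchors + rng.normal(0.0, config.jitter_sd, size=anchors.shape)
            extra = rng.uniform(0.0, fs, size=(counts[ch] - n_coloc, 2))
            for x, y in np.vstack([pts, extra]):
                rows.append(
                    {"nucleus_id": nucleus_id, "channel": ch, "x": x, "y": y}
                )
        rec = {"nucleus_id": nucleus_id, "n_coloc_true": n_coloc}
        rec.update({f"n_{ch}": counts[ch] for ch in config.channels})
        truth.append(rec)
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# TSV round-trip helpers (schemas shared with the CLI and analysis scripts)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "target": str})
    missing = {"sample_id", "target", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = {"sample_id", "group", "ct_tel", "ct_alb"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return df


def read_foci_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"nucleus_id": str, "channel": str})
    missing = {"nucleus_id", "channel", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"foci table missing columns {sorted(missing)}")
    return df
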