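"""Flat key=value run configuration shared by the CLI pipeline.

The file format is intentionally minimal and diff-able: one ``key = value``
per line, '#' comments, no nesting.  Unknown keys are rejected before any
stage runs; parsing then re-serializing a config reproduces it byte-
identically (modulo comments), which the pipeline relies on for parameter
stamping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from typing import get_type_hints

from .capseq import CapParams
from .classify import ClassifyParams
from .napseeker import SeekerParams
from .simulate import SimConfig
from .trim import TrimConfig

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with published defaults
    where the protocol states one (7, 2, 2, 100 nt, 2 samples, 20 reads,
    10 nt, 10 kb, 10 reads, 0.05)."""

    # simulator
    rng_seed: int = 0
    genome_length: int = 120_000
    gc_fraction: float = 0.5
    n_samples: int = 3
    reads_per_end: int = 10
    adapter_retention_prob: float = 0.5
    background_read_rate: float = 0.0
    # trimming
    trim_error_rate: float = 0.1
    trim_min_length: int = 15
    barcode_len: int = 6
    trim_min_overlap: int = 10
    # caller
    min_boundary_reads: int = 7
    min_boundary_fc: float = 2.0
    min_flank_fc: float = 2.0
    min_length: int = 100
    min_samples: int = 2
    min_summary: int = 20
    end_tolerance: int = 5
    multi_peak: bool = False
    # cap caller
    cap_min_count: int = 10
    cap_min_fc: float = 2.0
    cap_alpha: float = 0.05
    cap_window: int = 100
    # classifiers
    sli_end_tolerance: int = 0
    snotron_splice_tolerance: int = 10
    mirna_cluster_gap: int = 10_000
    mis_end_tolerance: int = 3
    # structure
    z_n_shuffles: int = 100
    z_shuffle_order: int = 2
    shape_min_depth: int = 100
    shape_ss_threshold: float = 0.7

    def seeker_params(self) -> SeekerParams:
        return SeekerParams(
            min_boundary_reads=self.min_boundary_reads,
            min_boundary_fc=self.min_boundary_fc,
            min_flank_fc=self.min_flank_fc,
            min_length=self.min_length,
            min_samples=self.min_samples,
            min_summary=self.min_summary,
            end_tolerance=self.end_tolerance,
            multi_peak=self.multi_peak,
        )

    def cap_params(self) -> CapParams:
        return CapParams(
            min_fc=self.cap_min_fc,
            min_count=self.cap_min_count,
            alpha=self.cap_alpha,
            window=self.cap_window,
        )

    def classify_params(self) -> ClassifyParams:
        return ClassifyParams(
            sli_end_tolerance=self.sli_end_tolerance,
            snotron_splice_tolerance=self.snotron_splice_tolerance,
            mirna_cluster_gap=self.mirna_cluster_gap,
            mis_end_tolerance=self.mis_end_tolerance,
        )

    def trim_config(self) -> TrimConfig:
        return TrimConfig(
            max_error_rate=self.trim_error_rate,
            min_length=self.trim_min_length,
            barcode5_len=self.barcode_len,
            barcode3_len=self.barcode_len,
            min_overlap=self.trim_min_overlap,
        )

    def sim_config(self) -> SimConfig:
        return SimConfig(
            rng_seed=self.rng_seed,
            genome_length=self.genome_length,
            gc_fraction=self.gc_fraction,
            n_samples=self.n_samples,
            reads_per_end=self.reads_per_end,
            adapter_retention_prob=self.adapter_retention_prob,
            background_read_rate=self.background_read_rate,
        )


def _parse_value(raw: str, typ) -> object:
    if typ is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"bad boolean {raw!r}")
    return typ(raw)


def load_config(path) -> RunConfig:
    """Parse a flat key=value file; unknown keys are an error."""
    hints = get_type_hints(RunConfig)
    known = {f.name: hints[f.name] for f in fields(RunConfig)}
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (x.strip() for x in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _parse_value(raw, known[key])
    return RunConfig(**values)


def dump_config(cfg: RunConfig) -> str:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in fields(RunConfig)]
    return "\n".join(lines) + "\n"


def parameter_stamp(cfg: RunConfig) -> str:
    """One-line provenance stamp written into output headers."""
    pairs = ", ".join(
        f"{f.name}={getattr(cfg, f.name)}"
        for f in dataclasses.fields(cfg)
    )
    return f"napkit v{__version__} [{pairs}]"


__all__ = ["RunConfig", "load_config", "dump_config", "parameter_stamp", "__version__"]
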