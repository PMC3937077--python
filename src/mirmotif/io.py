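"""Readers and writers for the package's plain-text formats.

Profile tables are TSV (or CSV, by extension): first column ``species_id``,
second ``role``, remaining columns numeric expression values under a header
row of time values.  Motifs are JSON; mature sequences are FASTA; run
configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .estimation import FitConfig
from .kinetics import TDMotif, TIMotif
from .profiles import ExpressionProfile, ProfileSet, TimeGrid
from .quality import DEFAULT_MODER_THRESHOLD
from .seqsim import AlignmentScoring, MatureSequence

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "read_fasta",
    "read_motif_json",
    "write_motif_json",
    "RunConfig",
    "write_manifest",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_profile_table(path) -> ProfileSet:
    """Parse a profile table into a validated :class:`ProfileSet`."""
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 4:
        raise ValueError(
            f"{path}: expected species_id, role and at least 2 time columns"
        )
    time_cols = list(df.columns[2:])
    try:
        grid = TimeGrid(tuple(float(c) for c in time_cols))
    except ValueError as exc:
        raise ValueError(f"{path}: bad time header: {exc}") from exc
    dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate species_id {sorted(set(dupes))}")
    profiles = ProfileSet(grid)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid, role = row[0], row[1]
        values = []
        for col_no, cell in enumerate(row[2:], start=3):
            try:
                values.append(float(cell))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {row_no}, "
                    f"column {col_no} (species {sid!r})"
                ) from None
        profiles.add(ExpressionProfile(sid, role, np.array(values), grid))
    return profiles


def write_profile_table(profiles: ProfileSet, path) -> None:
    """Write the identical dialect :func:`read_profile_table` parses."""
    sep = _sep_for(path)
    header = ["species_id", "role"] + [repr(t) for t in profiles.grid.points]
    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for prof in profiles:
            cells = [prof.species_id, prof.role] + [repr(float(v)) for v in prof.values]
            fh.write(sep.join(cells) + "\n")


def read_fasta(path) -> List[MatureSequence]:
    """FASTA reader; ids are header tokens up to the first whitespace,
    sequences are uppercased with T normalized to U."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        records.append(MatureSequence(rec.id, seq))
    return records


def read_motif_json(path):
    """Motif JSON: ``{"type": "TI"|"TD", ...role lists...}``."""
    with open(path) as fh:
        spec = json.load(fh)
    kind = spec.get("type")
    if kind == "TI":
        return TIMotif(spec["protein"], spec["mrna"], tuple(spec.get("inhibitors", ())))
    if kind == "TD":
        return TDMotif(spec["mrna"], spec["mirna"],
                       tuple(spec.get("repressors", ())),
                       tuple(spec.get("activators", ())))
    raise ValueError(f"{path}: motif type must be 'TI' or 'TD', got {kind!r}")


def write_motif_json(motif, path) -> None:
    if isinstance(motif, TIMotif):
        spec = {"type": "TI", "protein": motif.protein_id, "mrna": motif.mrna_id,
                "inhibitors": list(motif.inhibitors)}
    elif isinstance(motif, TDMotif):
        spec = {"type": "TD", "mrna": motif.mrna_id, "mirna": motif.mirna_id,
                "repressors": list(motif.repressors),
                "activators": list(motif.activators)}
    else:
        raise TypeError(f"unsupported motif type {type(motif).__name__}")
    with open(path, "w") as fh:
        json.dump(spec, fh, indent=2)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a pipeline run; echoed into every output."""

    epsilon: float = 0.15
    fit: FitConfig = field(default_factory=FitConfig)
    moder_threshold: float = DEFAULT_MODER_THRESHOLD
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    nwa_threshold: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.epsilon <= 0 or self.moder_threshold <= 0 or self.nwa_threshold <= 0:
            raise ValueError("configuration values must be positive")
        # keep the fit config's verdict threshold in sync
        if self.fit.moder_threshold != self.moder_threshold:
            object.__setattr__(
                self, "fit",
                dataclasses.replace(self.fit, moder_threshold=self.moder_threshold),
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit_kwargs = raw.pop("fit", {})
        if "s_by_k" in fit_kwargs:
            fit_kwargs["s_by_k"] = {int(k): int(v) for k, v in fit_kwargs["s_by_k"].items()}
        scoring_kwargs = raw.pop("scoring", {})
        return cls(fit=FitConfig(**fit_kwargs),
                   scoring=AlignmentScoring(**scoring_kwargs), **raw)

    def as_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "fit": self.fit.as_dict(),
            "moder_threshold": self.moder_threshold,
            "scoring": {"match": self.scoring.match, "mismatch": self.scoring.mismatch,
                        "gap": self.scoring.gap},
            "nwa_threshold": self.nwa_threshold,
            "seed": self.seed,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: RunConfig, inputs: Dict[str, str]) -> None:
    """Reproducibility manifest: resolved config, input checksums, version."""
    from . import __version__

    manifest = {
        "version": __version__,
        "config": config.as_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
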