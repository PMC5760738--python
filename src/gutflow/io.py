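"""Tabular I/O, run configuration, and ground-truth sidecars.

All on-disk formats are delimited text (comma by default, tab accepted)
with header rows, plus YAML for configuration and ground-truth records —
the domain data are small count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .egestion import FecalTimeSeries, InoculumComposition
from .errors import ValidationError
from .fate import FateSample
from .phase_model import CompartmentChain

__all__ = [
    "RunConfig",
    "read_table",
    "read_samples",
    "write_samples",
    "read_inoculum",
    "write_inoculum",
    "read_fate_samples",
    "write_fate_samples",
    "read_chains",
    "write_chains",
    "read_ground_truth",
    "write_ground_truth",
]

PathLike = Union[str, Path]

SAMPLE_COLUMNS = (
    ["sample_id", "treatment", "replicate_day", "n_flies"]
    + [f"b{i}" for i in range(1, 6)]
    + [f"s{i}" for i in range(1, 6)]
)


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    return pd.read_csv(path, sep=None, engine="python")


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table missing columns: {missing}")


def read_samples(path: PathLike) -> list[FecalTimeSeries]:
    """Read fecal time-series samples (one row per vial)."""
    df = read_table(path)
    _require(df, SAMPLE_COLUMNS, "sample")
    samples = []
    for _, row in df.iterrows():
        def flag(col: str) -> Optional[bool]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return bool(row[col])

        samples.append(
            FecalTimeSeries(
                sample_id=str(row["sample_id"]),
                treatment=str(row["treatment"]),
                replicate_day=row["replicate_day"],
                n_flies=int(row["n_flies"]),
                bacteria_counts=tuple(row[f"b{i}"] for i in range(1, 6)),
                sphere_counts=tuple(row[f"s{i}"] for i in range(1, 6)),
                presence_24h=flag("presence_24h"),
                presence_48h=flag("presence_48h"),
            )
        )
    return samples


def write_samples(samples: Sequence[FecalTimeSeries], path: PathLike) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "treatment": s.treatment,
            "replicate_day": s.replicate_day,
            "n_flies": s.n_flies,
        }
        row.update({f"b{i + 1}": c for i, c in enumerate(s.bacteria_counts)})
        row.update({f"s{i + 1}": c for i, c in enumerate(s.sphere_counts)})
        row["presence_24h"] = s.presence_24h
        row["presence_48h"] = s.presence_48h
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_inoculum(path: PathLike) -> dict[str, InoculumComposition]:
    df = read_table(path)
    _require(df, ["treatment", "bacteria_per_field", "spheres_per_field"], "inoculum")
    return {
        str(row["treatment"]): InoculumComposition(
            float(row["bacteria_per_field"]), float(row["spheres_per_field"])
        )
        for _, row in df.iterrows()
    }


def write_inoculum(inoculum: dict[str, InoculumComposition], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "treatment": name,
                "bacteria_per_field": inoc.bacteria_per_field,
                "spheres_per_field": inoc.spheres_per_field,
            }
            for name, inoc in inoculum.items()
        ]
    ).to_csv(path, index=False)


FATE_COLUMNS = [
    "replicate_day",
    "fly_treatment",
    "n_flies",
    "ingested",
    "egested",
    "retained_cfu",
    "conversion",
]


def read_fate_samples(path: PathLike) -> list[FateSample]:
    df = read_table(path)
    _require(df, FATE_COLUMNS, "fate")
    return [
        FateSample(
            replicate_day=row["replicate_day"],
            fly_treatment=str(row["fly_treatment"]),
            n_flies=int(row["n_flies"]),
            ingested=float(row["ingested"]),
            egested=float(row["egested"]),
            retained_cfu=float(row["retained_cfu"]),
            conversion=float(row["conversion"]),
        )
        for _, row in df.iterrows()
    ]


def write_fate_samples(samples: Sequence[FateSample], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "replicate_day": s.replicate_day,
                "fly_treatment": s.fly_treatment,
                "n_flies": s.n_flies,
                "ingested": s.ingested,
                "egested": s.egested,
                "retained_cfu": s.retained_cfu,
                "conversion": s.conversion,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_chains(path: PathLike) -> dict[str, CompartmentChain]:
    """Read named compartment chains (columns model, compartment_index, m, r)."""
    df = read_table(path)
    _require(df, ["model", "compartment_index", "m", "r"], "chain")
    chains = {}
    for model, group in df.groupby("model", sort=True):
        g = group.sort_values("compartment_index")
        try:
            chains[str(model)] = CompartmentChain(
                tuple(g["m"].astype(float)), tuple(g["r"].astype(float))
            )
        except ValidationError as exc:
            raise ValidationError(f"model {model!r}: {exc}") from exc
    return chains


def write_chains(chains: dict[str, CompartmentChain], path: PathLike) -> None:
    rows = []
    for name, chain in chains.items():
        for i, (m, r) in enumerate(zip(chain.m, chain.r)):
            rows.append({"model": name, "compartment_index": i, "m": m, "r": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth(truth: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_ground_truth(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class RunConfig:
    """Run configuration shared by the CLI subcommands."""

    alpha: float = 0.05
    bin_convention: str = "endpoint"
    rule: str = "or"
    seed: int = 0
    out_dir: Optional[Path] = None
    samples_path: Optional[Path] = None
    inoculum_path: Optional[Path] = None
    fate_path: Optional[Path] = None
    chains_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("out_dir", "samples_path", "inoculum_path", "fate_path", "chains_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)
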