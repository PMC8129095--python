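"""Plain-text I/O: trace CSV + JSON sidecars, DE TSV tables, GMT gene sets."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, LfpTrace

__all__ = [
    "write_trace", "read_trace", "write_ground_truth", "read_ground_truth",
    "write_de_table", "read_de_table", "write_gmt", "read_gmt",
]


def write_trace(trace: LfpTrace, directory: str | Path) -> Path:
    """Write a trace as <slice>_<ka>nM.csv (time_s, amplitude) + .json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{trace.slice_id}_{trace.ka_nm:g}nM"
    csv_path = directory / f"{stem}.csv"
    pd.DataFrame({"time_s": trace.times, "amplitude": trace.samples}).to_csv(
        csv_path, index=False)
    (directory / f"{stem}.json").write_text(json.dumps(trace.metadata(), indent=1))
    return csv_path


def read_trace(csv_path: str | Path) -> LfpTrace:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    return LfpTrace(samples=df["amplitude"].to_numpy(), **meta)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "spike_times": truth.spike_times.tolist(),
        "iid_times": truth.iid_times.tolist(),
        "gamma_freq": truth.gamma_freq,
        "gamma_amp": truth.gamma_amp,
        "noise_sd": truth.noise_sd,
    }, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(spike_times=np.asarray(d["spike_times"]),
                       iid_times=np.asarray(d["iid_times"]),
                       gamma_freq=d["gamma_freq"], gamma_amp=d["gamma_amp"],
                       noise_sd=d["noise_sd"])


def write_de_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "logFC", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    lines = [f"{name}\t{description}\t" + "\t".join(sorted(set(genes)))
             for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets
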