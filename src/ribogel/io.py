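"""Tabular (TSV) and JSON interchange.

TSV with a header row, tab separator, UTF-8 and '.' decimal is the canonical
tabular dialect (diff-able, opens in any gel-quantification spreadsheet);
configs and reports are JSON. Column names are fixed per table kind:

* lane profile:      ``position  intensity``
* marker ladder:     ``size_nt  position``
* fragments:         ``length_nt  signal``
* band table:        ``position  intensity  timepoint``
* size distribution: ``bin_lo  bin_hi  signal_fraction  molar_fraction``
* termination:       ``position  mean_T  sd_T  <one column per timepoint>``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import config_hash
from .densitometry import LaneProfile, MarkerLadder, SizeDistribution
from .estimators import BandTable, TerminationProfile
from .simulate import FragmentSet

__all__ = [
    "SchemaError",
    "read_lane", "write_lane",
    "read_ladder", "write_ladder",
    "read_fragments", "write_fragments",
    "read_bands", "write_bands",
    "write_distribution",
    "write_termination",
    "provenance_block", "write_json",
]


class SchemaError(ValueError):
    """A tabular input lacks a required column or has malformed values."""


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_lane(path) -> LaneProfile:
    df = _read_tsv(path, ("position", "intensity"))
    return LaneProfile(df["position"].to_numpy(float), df["intensity"].to_numpy(float))


def write_lane(profile: LaneProfile, path) -> None:
    _write_tsv(
        pd.DataFrame({"position": profile.positions, "intensity": profile.intensities}),
        path,
    )


def read_ladder(path) -> MarkerLadder:
    df = _read_tsv(path, ("size_nt", "position"))
    return MarkerLadder(df["size_nt"].to_numpy(float), df["position"].to_numpy(float))


def write_ladder(ladder: MarkerLadder, path) -> None:
    _write_tsv(
        pd.DataFrame({"size_nt": ladder.sizes, "position": ladder.positions}), path
    )


def read_fragments(path) -> FragmentSet:
    df = _read_tsv(path, ("length_nt", "signal"))
    return FragmentSet(df["length_nt"].to_numpy(np.int64), df["signal"].to_numpy(float))


def write_fragments(fragments: FragmentSet, path) -> None:
    _write_tsv(
        pd.DataFrame({"length_nt": fragments.lengths, "signal": fragments.signals}),
        path,
    )


def read_bands(path) -> BandTable:
    df = _read_tsv(path, ("position", "intensity", "timepoint"))
    records = [
        (str(r.position), float(r.intensity), str(r.timepoint))
        for r in df.itertuples(index=False)
    ]
    return BandTable.from_records(records)


def write_bands(bands: BandTable, path) -> None:
    rows = [
        {"position": pos, "intensity": bands.intensities[i, j], "timepoint": tp}
        for j, tp in enumerate(bands.timepoints)
        for i, pos in enumerate(bands.positions)
    ]
    _write_tsv(pd.DataFrame(rows), path)


def write_distribution(dist: SizeDistribution, path) -> None:
    molar = (dist.molar_fraction if dist.molar_fraction is not None
             else np.full_like(dist.signal_fraction, np.nan))
    _write_tsv(
        pd.DataFrame({
            "bin_lo": dist.bin_edges[:-1],
            "bin_hi": dist.bin_edges[1:],
            "signal_fraction": dist.signal_fraction,
            "molar_fraction": molar,
        }),
        path,
    )


def write_termination(profile: TerminationProfile, path) -> None:
    data = {
        "position": profile.positions,
        "mean_T": profile.mean,
        "sd_T": profile.sd,
    }
    for j, tp in enumerate(profile.timepoints):
        data[f"T_{tp}"] = profile.per_timepoint[:, j]
    _write_tsv(pd.DataFrame(data), path)


def provenance_block(config, seed: int) -> dict:
    """Provenance embedded in every stochastic run's JSON output.

    Deliberately timestamp-free so reruns with the same config are
    bit-identical.
    """
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "ribogel_version": __version__,
    }


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
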