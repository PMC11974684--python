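"""File formats: time-course CSV, multi-model PDB ensembles, assay CSVs,
result tables, and the run configuration.

Time courses travel as long-format CSV, one row per replicate x time point:

    replicate,time_s,pct_supercoiled,pct_nicked,pct_linear

Rows whose three fractions sum outside [95, 105] are rejected by name — gel
quantification drifts, but not that far.  Coordinate ensembles travel as
multi-model PDB (MODEL/ENDMDL records, or one implicit frame); HETATM
records are ignored and insertion codes are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import MeltCurve, TransCurve
from .fitting import AggregateRates, FitResult, Replicate, TimeCourseDataset
from .geometry import FrameEnsemble
from .model import KineticParams, ObservedFractions

__all__ = [
    "TIMECOURSE_COLUMNS",
    "RunConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_pdb_frames",
    "write_pdb_frames",
    "read_melt_csv",
    "read_trans_csv",
    "fits_to_frame",
    "write_fit_results",
    "load_config",
]

TIMECOURSE_COLUMNS = ["replicate", "time_s", "pct_supercoiled", "pct_nicked", "pct_linear"]

_ROW_SUM_BAND = (95.0, 105.0)


def read_timecourse_csv(path) -> TimeCourseDataset:
    """Parse and validate a long-format topology time-course CSV.

    Rows are grouped by replicate and sorted by time.  Missing columns,
    non-numeric cells, duplicate (replicate, time) pairs and rows whose
    fractions sum outside [95, 105] are reported with their CSV line numbers
    (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    df = df[TIMECOURSE_COLUMNS].copy()
    df["line"] = df.index + 2  # header occupies line 1

    numeric_cols = TIMECOURSE_COLUMNS[1:]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[converted.isna(), "line"].tolist()
        if bad:
            raise ValueError(f"{path.name}: non-numeric {col!r} at line(s) {bad}")
        df[col] = converted

    dup = df.duplicated(subset=["replicate", "time_s"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path.name}: duplicate (replicate, time) rows at line(s) "
            f"{df.loc[dup, 'line'].tolist()}"
        )

    sums = df[["pct_supercoiled", "pct_nicked", "pct_linear"]].sum(axis=1)
    lo, hi = _ROW_SUM_BAND
    bad = df.loc[(sums < lo) | (sums > hi), "line"].tolist()
    if bad:
        raise ValueError(
            f"{path.name}: fraction sums outside [{lo}, {hi}] at line(s) {bad}"
        )

    replicates = []
    for rep_id, group in df.groupby("replicate", sort=True):
        group = group.sort_values("time_s")
        obs = ObservedFractions(
            times=group["time_s"].to_numpy(),
            totSC=group["pct_supercoiled"].to_numpy(),
            totNICK=group["pct_nicked"].to_numpy(),
            lin=group["pct_linear"].to_numpy(),
        )
        replicates.append(Replicate(replicate_id=str(rep_id), observed=obs))
    if not replicates:
        raise ValueError(f"{path.name}: no data rows")
    return TimeCourseDataset(replicates=replicates)


def write_timecourse_csv(dataset: TimeCourseDataset, path) -> None:
    rows = []
    for rep in dataset:
        obs = rep.observed
        for t, sc, nick, lin in zip(obs.times, obs.totSC, obs.totNICK, obs.lin):
            rows.append((rep.replicate_id, t, sc, nick, lin))
    df = pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_pdb_frames(path, chain: str | None = None) -> FrameEnsemble:
    """Read a (multi-model) PDB file into a frame ensemble.

    Frames are MODEL/ENDMDL blocks, or one implicit frame.  HETATM records
    are dropped; insertion codes are rejected (residue selection here is by
    author residue number only).  ``chain`` filters to one chain ID; by
    default the first chain present is used when the file has several.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"{path.name}: cannot parse PDB structure: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path.name}: no ATOM records")

    mask = ~stack.hetero
    if not mask.any():
        raise ValueError(f"{path.name}: no non-HETATM ATOM records")
    chains = np.unique(stack.chain_id[mask])
    if chain is not None:
        if chain not in chains:
            raise ValueError(f"{path.name}: chain {chain!r} not present (found {chains.tolist()})")
        mask &= stack.chain_id == chain
    elif chains.size > 1:
        mask &= stack.chain_id == chains[0]

    ins = stack.ins_code[mask]
    nonblank = np.array([str(c).strip() != "" for c in ins])
    if nonblank.any():
        raise ValueError(
            f"{path.name}: insertion codes present "
            f"({sorted(set(str(c) for c in ins[nonblank]))}); not supported"
        )

    coords = stack.coord[:, mask, :]
    return FrameEnsemble(
        coords=coords,
        res_ids=stack.res_id[mask],
        atom_names=stack.atom_name[mask].astype(object),
        elements=stack.element[mask].astype(object),
    )


def write_pdb_frames(ensemble: FrameEnsemble, path) -> None:
    """Write an ensemble as multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = ensemble.coords
    stack.chain_id = np.full(n, "A")
    stack.res_id = ensemble.res_ids
    stack.res_name = np.full(n, "GLY")
    stack.atom_name = np.array([str(a)[:4] for a in ensemble.atom_names])
    stack.element = np.array([str(e).upper() for e in ensemble.resolved_elements()])
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _read_two_column_csv(path, col_x: str, col_y: str):
    path = Path(path)
    df = pd.read_csv(path)
    for col in (col_x, col_y):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="raise")
    df = df.sort_values(col_x)
    return df[col_x].to_numpy(), df[col_y].to_numpy()


def read_melt_csv(path) -> MeltCurve:
    """CSV with columns temperature_c,fluorescence."""
    temps, fluor = _read_two_column_csv(path, "temperature_c", "fluorescence")
    return MeltCurve(temperatures=temps, fluorescence=fluor)


def read_trans_csv(path) -> TransCurve:
    """CSV with columns time_s,fluorescence."""
    times, fluor = _read_two_column_csv(path, "time_s", "fluorescence")
    return TransCurve(times=times, fluorescence=fluor)


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    rows = [
        {
            "replicate": f.replicate_id,
            "ka": f.params.ka,
            "kb": f.params.kb,
            "kini": f.params.kini,
            "kini2": f.params.kini2,
            "loss": f.loss,
            "n_points": f.n_points,
            "converged": f.converged,
            "variant": f.variant,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def write_fit_results(fits: list[FitResult], agg: AggregateRates, out_dir) -> None:
    """Per-replicate rate table (CSV) plus aggregate mean +/- s.d. (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fits_to_frame(fits).to_csv(out_dir / "fits.csv", index=False, float_format="%.8g")
    payload = {
        "ka_mean": agg.ka_mean,
        "ka_sd": agg.ka_sd,
        "kb_mean": agg.kb_mean,
        "kb_sd": agg.kb_sd,
        "n_replicates": agg.n,
        "ka_values": list(agg.ka_values),
        "kb_values": list(agg.kb_values),
        "single_replicate": agg.single_replicate,
    }
    (out_dir / "aggregate.json").write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class RunConfig:
    """Validated knobs for a pipeline run; unknown keys are rejected."""

    variant: str = "as_printed"
    n_restarts: int = 10
    bounds: tuple[float, float] = (0.0, 100.0)
    fraction_sd: float = 2.0
    domain_preset: str | None = None
    rec2: tuple[int, int] | None = None
    nuc: tuple[int, int] | None = None
    cutoff: float = 3.5
    seed: int | None = None
    out_dir: str = "results"

    def __post_init__(self):
        from .model import VARIANTS

        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        lo, hi = self.bounds
        if lo < 0 or hi <= lo:
            raise ValueError(f"bounds must satisfy 0 <= lo < hi, got {self.bounds}")
        if self.fraction_sd < 0:
            raise ValueError("fraction_sd must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys loudly."""
    import yaml

    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path.name}: unknown config key(s) {unknown}")
    for key in ("bounds", "rec2", "nuc"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
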