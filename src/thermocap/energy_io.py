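"""Reading, validating, trimming and block-splitting MD energy time series.

The unit of data is one :class:`EnergyTrajectory` — the sampled energies of a
single simulation at one temperature setpoint.  A set of runs at distinct
setpoints forms a :class:`TemperatureEnsemble`, the input of the derivative
and fluctuation heat-capacity estimators.

Supported on-disk formats are plain delimited tables (CSV/TSV/whitespace,
``#`` comments, optional header) and the GROMACS XVG energy-export dialect
(``#``/``@`` metadata lines, whitespace-separated data, legends used for
column auto-mapping).  Energies are stored in kcal/mol internally; XVG files
are assumed to be in kJ/mol (the dialect's convention) and converted on read
unless told otherwise.
"""

from __future__ import annotations

import io
import json
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KCAL_PER_KJ

__all__ = [
    "EnergyTrajectory",
    "TemperatureEnsemble",
    "read_energy_table",
    "read_xvg",
    "write_energy_table",
    "trim_equilibration",
    "split_blocks",
]

#: Energy components a trajectory may carry, in canonical column order.
COMPONENTS = ("e_tot", "u_tot", "ke", "u_group")

_ETOT_TOL = 1e-6


@dataclass(frozen=True)
class EnergyTrajectory:
    """Sampled energies of one MD run at a fixed temperature setpoint.

    Parameters
    ----------
    temperature_setpoint : float
        Thermostat target temperature, K.
    time : ndarray
        Sample times, ps, strictly increasing.
    e_tot : ndarray
        Total energy per sample, kcal/mol.
    u_tot, ke, u_group : ndarray, optional
        Total potential energy, kinetic energy, and a user-defined group
        potential (e.g. protein-only), kcal/mol.
    timestep : float, optional
        Integrator timestep, fs.
    n_df : int, optional
        Number of degrees of freedom of the simulated system (used for the
        kinetic N_df·R/2 correction of potential-only heat capacities).
    label : str
        Free-text tag.
    """

    temperature_setpoint: float
    time: np.ndarray
    e_tot: np.ndarray | None = None
    u_tot: np.ndarray | None = None
    ke: np.ndarray | None = None
    u_group: np.ndarray | None = None
    timestep: float | None = None
    n_df: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.temperature_setpoint > 0:
            raise ValueError(
                f"temperature_setpoint must be > 0 K, got {self.temperature_setpoint}"
            )
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        n = self.time.size
        if n < 2:
            raise ValueError(f"trajectory needs at least 2 samples, got {n}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in COMPONENTS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size != n:
                raise ValueError(
                    f"column {name!r} has length {arr.size}, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"column {name!r} contains non-finite values")
        if self.e_tot is not None and self.u_tot is not None and self.ke is not None:
            resid = np.abs(self.e_tot - (self.u_tot + self.ke))
            bound = _ETOT_TOL * np.maximum(1.0, np.abs(self.e_tot))
            if np.any(resid > bound):
                i = int(np.argmax(resid - bound))
                raise ValueError(
                    "energy bookkeeping violated: |e_tot - (u_tot + ke)| = "
                    f"{resid[i]:.3g} at sample {i} exceeds tolerance"
                )
        if self.n_df is not None and self.n_df < 0:
            raise ValueError("n_df must be non-negative")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def components(self) -> tuple[str, ...]:
        """Names of the energy components present."""
        return tuple(c for c in COMPONENTS if getattr(self, c) is not None)

    def component(self, name: str) -> np.ndarray:
        """Return one component array, raising if absent."""
        if name not in COMPONENTS:
            raise KeyError(f"unknown component {name!r}; choose from {COMPONENTS}")
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"component {name!r} not present in trajectory {self.label!r}")
        return arr

    def slice(self, start: int, stop: int) -> "EnergyTrajectory":
        """Sub-trajectory of samples ``start:stop`` (validated)."""
        kw = {c: (getattr(self, c)[start:stop] if getattr(self, c) is not None else None)
              for c in COMPONENTS}
        return EnergyTrajectory(
            temperature_setpoint=self.temperature_setpoint,
            time=self.time[start:stop],
            timestep=self.timestep,
            n_df=self.n_df,
            label=self.label,
            **kw,
        )


@dataclass(frozen=True)
class TemperatureEnsemble:
    """Runs of the same system at ≥ 2 distinct temperature setpoints."""

    trajectories: tuple[EnergyTrajectory, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        trajs = tuple(self.trajectories)
        object.__setattr__(self, "trajectories", trajs)
        if len(trajs) < 2:
            raise ValueError("ensemble needs at least 2 trajectories")
        temps = [t.temperature_setpoint for t in trajs]
        if len(set(temps)) != len(temps):
            raise ValueError(f"temperature setpoints must be pairwise distinct: {temps}")
        comps = {t.components for t in trajs}
        if len(comps) != 1:
            raise ValueError(f"all members must expose the same components, got {comps}")
        ndfs = {t.n_df for t in trajs if t.n_df is not None}
        if len(ndfs) > 1:
            raise ValueError(f"n_df differs across members: {sorted(ndfs)}")

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t.temperature_setpoint for t in self.trajectories])

    @property
    def n_df(self) -> int | None:
        for t in self.trajectories:
            if t.n_df is not None:
                return t.n_df
        return None

    def sorted(self) -> "TemperatureEnsemble":
        order = np.argsort(self.temperatures)
        return TemperatureEnsemble(tuple(self.trajectories[i] for i in order))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _coerce_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    # float() is correctly rounded, so parsing is lossless for values written
    # with 17 significant digits; it also lets us report the offending row.
    out = {}
    for col in df.columns:
        vals = np.empty(len(df))
        for row, tok in enumerate(df[col]):
            try:
                vals[row] = float(tok)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} in column {col!r} "
                    f"at data row {row}"
                ) from None
        out[col] = vals
    return pd.DataFrame(out)


def read_energy_table(
    path: str | os.PathLike,
    column_map: dict[str, str | int] | None = None,
    temperature: float | None = None,
    *,
    energy_unit: str = "kcal",
    timestep: float | None = None,
    n_df: int | None = None,
    label: str | None = None,
) -> EnergyTrajectory:
    """Read a delimited text table into an :class:`EnergyTrajectory`.

    ``column_map`` maps trajectory fields (``time``, ``e_tot``, ``u_tot``,
    ``ke``, ``u_group``) to header names or 0-based column indices.  With no
    map, canonical header names are used directly.  ``#`` starts a comment;
    the delimiter is auto-detected among comma/tab/whitespace.  A JSON
    sidecar ``<path>.json`` written by :func:`write_energy_table` supplies
    setpoint/timestep/n_df/label when not given explicitly.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    sidecar = path + ".json"
    meta = {}
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    if temperature is None:
        temperature = meta.get("temperature_setpoint")
    if temperature is None:
        raise ValueError(f"{path}: temperature setpoint not given and no sidecar found")
    timestep = timestep if timestep is not None else meta.get("timestep")
    n_df = n_df if n_df is not None else meta.get("n_df")
    label = label if label is not None else meta.get("label", os.path.basename(path))

    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data lines")
    # Delimiter sniffing on the first data line.
    first = lines[0]
    if "," in first:
        sep: str | None = ","
    elif "\t" in first:
        sep = "\t"
    else:
        sep = r"\s+"
    # Header detection: any field on the first line that is not a number.
    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    toks = re.split(sep if sep != r"\s+" else r"\s+", first.strip())
    has_header = not all(_is_number(t) for t in toks if t)
    df = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep=sep,
        engine="python",
        header=0 if has_header else None,
        dtype=str,
        skipinitialspace=True,
    )
    if has_header:
        df.columns = [str(c).strip() for c in df.columns]
    df = _coerce_numeric(df, path)

    if column_map is None:
        column_map = {c: c for c in ("time",) + COMPONENTS if c in df.columns}
        if "time" not in column_map:
            raise ValueError(
                f"{path}: no 'time' column found; provide a column_map "
                f"(available: {list(df.columns)})"
            )
    cols: dict[str, np.ndarray] = {}
    for fld, key in column_map.items():
        if isinstance(key, int):
            if key >= df.shape[1]:
                raise ValueError(f"{path}: column index {key} out of range")
            cols[fld] = df.iloc[:, key].to_numpy()
        else:
            if key not in df.columns:
                raise ValueError(
                    f"{path}: mapped column {key!r} not in header {list(df.columns)}"
                )
            cols[fld] = df[key].to_numpy()
    if "time" not in cols:
        raise ValueError(f"{path}: column_map must map 'time'")

    scale = 1.0 if energy_unit == "kcal" else KCAL_PER_KJ
    kw = {c: cols[c] * scale for c in COMPONENTS if c in cols}
    return EnergyTrajectory(
        temperature_setpoint=float(temperature),
        time=cols["time"],
        timestep=timestep,
        n_df=n_df,
        label=label,
        **kw,
    )


# XVG legend strings recognised for auto-mapping (GROMACS `gmx energy` names).
_XVG_LEGENDS = {
    "total energy": "e_tot",
    "potential": "u_tot",
    "kinetic en.": "ke",
    "kinetic energy": "ke",
}


def read_xvg(
    path: str | os.PathLike,
    temperature: float | None = None,
    column_map: dict[str, int] | None = None,
    *,
    energy_unit: str = "kJ",
    timestep: float | None = None,
    n_df: int | None = None,
    label: str | None = None,
) -> EnergyTrajectory:
    """Read a GROMACS XVG energy export.

    Lines starting ``#`` or ``@`` are metadata.  Legend lines
    (``@ s0 legend "Total Energy"``) auto-map data columns when
    ``column_map`` is omitted; column 0 is always time.  ``column_map``
    maps field names to 0-based *data* column indices.  Energies default
    to kJ/mol (the dialect convention) and are converted to kcal/mol.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    legends: dict[int, str] = {}
    rows: list[list[float]] = []
    legend_re = re.compile(r"@\s*s(\d+)\s+legend\s+\"(.*)\"")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                m = legend_re.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                continue
            toks = line.split()
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric data line") from exc
    if not rows:
        raise ValueError(f"{path}: no data lines")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    data = np.asarray(rows, dtype=float)

    if column_map is None:
        column_map = {}
        for s_idx, text in legends.items():
            fld = _XVG_LEGENDS.get(text.strip().lower())
            if fld is not None:
                column_map[fld] = s_idx + 1  # data sets start at column 1
        if not column_map:
            if data.shape[1] < 2:
                raise ValueError(f"{path}: single-column file with no legends")
            column_map = {"e_tot": 1}
    missing = [v for v in column_map.values() if v >= data.shape[1]]
    if missing:
        raise ValueError(f"{path}: mapped column index {missing[0]} out of range")

    scale = KCAL_PER_KJ if energy_unit == "kJ" else 1.0
    kw = {fld: data[:, idx] * scale for fld, idx in column_map.items()}
    if temperature is None:
        raise ValueError(f"{path}: temperature setpoint is required")
    return EnergyTrajectory(
        temperature_setpoint=float(temperature),
        time=data[:, 0],
        timestep=timestep,
        n_df=n_df,
        label=label if label is not None else os.path.basename(path),
        **kw,
    )


def write_energy_table(traj: EnergyTrajectory, path: str | os.PathLike) -> None:
    """Write the canonical CSV (+ JSON sidecar) for a trajectory.

    Columns are ``time`` plus whichever of e_tot/u_tot/ke/u_group are
    present, full float precision so a read round-trips bit-exactly.
    """
    path = os.fspath(path)
    cols = {"time": traj.time}
    cols.update({c: getattr(traj, c) for c in COMPONENTS if getattr(traj, c) is not None})
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "temperature_setpoint": traj.temperature_setpoint,
        "timestep": traj.timestep,
        "n_df": traj.n_df,
        "label": traj.label,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Trimming / blocking
# ---------------------------------------------------------------------------

def trim_equilibration(
    traj: EnergyTrajectory,
    discard: float = 0.1,
    *,
    mode: str = "fraction",
) -> EnergyTrajectory:
    """Drop the initial equilibration part of a trajectory.

    ``mode='fraction'`` discards the first ``discard`` fraction of samples
    (default 10%); ``mode='time'`` discards all samples with
    ``time <= discard`` (ps).
    """
    n = len(traj)
    if mode == "fraction":
        if not 0 <= discard < 1:
            raise ValueError(f"fraction must be in [0, 1), got {discard}")
        start = int(np.floor(discard * n))
    elif mode == "time":
        if discard < 0 or discard >= traj.time[-1]:
            raise ValueError(
                f"discard time {discard} outside [0, {traj.time[-1]}) ps"
            )
        start = int(np.searchsorted(traj.time, discard, side="right"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n - start < 2:
        raise ValueError(f"trim would leave {n - start} samples (< 2)")
    if start == 0:
        return traj
    return traj.slice(start, n)


def split_blocks(traj: EnergyTrajectory, n_blocks: int = 2) -> list[EnergyTrajectory]:
    """Split into contiguous, non-overlapping blocks covering every sample.

    Block sizes differ by at most one (longer blocks first).
    """
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be ≥ 2, got {n_blocks}")
    n = len(traj)
    if n < 2 * n_blocks:
        raise ValueError(f"{n} samples cannot form {n_blocks} blocks of ≥ 2")
    base, extra = divmod(n, n_blocks)
    blocks = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < extra else 0)
        blocks.append(traj.slice(start, start + size))
        start += size
    return blocks
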