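"""File formats: PDB structures, charge tables, CSV time-series dialects
and the YAML study configuration.

Units are fixed and named at every file boundary — time_ns, mux/muy/muz in
e·nm, rmsd_nm, fx/fy/fz/fmag in eV/Å — and never autodetected: silent unit
errors are the dominant failure mode in this domain.  PDB coordinates (Å)
are converted to nm on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser

from .constants import NM_PER_ANGSTROM
from .orientation import DipoleTrajectory, OrientationSeries
from .rotor import DamageParams
from .study import StudyConfig

__all__ = [
    "Structure",
    "read_structure",
    "read_charges",
    "read_timeseries",
    "write_timeseries",
    "dipole_trajectory_to_frame",
    "dipole_trajectory_from_csv",
    "orientation_series_from_csv",
    "load_study_config",
    "save_study_config",
    "TIMESERIES_DIALECTS",
]


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """Parsed structure: coordinates in nm plus per-atom metadata."""

    coordinates: np.ndarray  # (N, 3), nm
    names: list
    elements: list
    masses: np.ndarray  # amu
    serials: np.ndarray
    residue_names: list
    residue_ids: np.ndarray  # 1-based, as in the file

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.coordinates).sum(axis=0) / m.sum()

    def ca_only(self) -> "Structure":
        mask = np.array([n.strip() == "CA" for n in self.names])
        return Structure(
            coordinates=self.coordinates[mask],
            names=[n for n, k in zip(self.names, mask) if k],
            elements=[e for e, k in zip(self.elements, mask) if k],
            masses=self.masses[mask],
            serials=self.serials[mask],
            residue_names=[r for r, k in zip(self.residue_names, mask) if k],
            residue_ids=self.residue_ids[mask],
        )


def _element_from_name(name: str) -> str:
    # protein/heteroatom PDB names start with the element; prefer the
    # one-letter reading (so "CA" is a C-alpha carbon, not calcium)
    stripped = "".join(c for c in name.strip() if c.isalpha())
    if not stripped:
        return ""
    if stripped[0].upper() in atom_weights:
        return stripped[0].upper()
    if stripped[:2].capitalize() in atom_weights:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _mass_for_element(element: str, atom_name: str) -> float:
    el = element.strip().capitalize()
    if el in atom_weights:
        return float(atom_weights[el])
    inferred = _element_from_name(atom_name)
    if inferred.capitalize() in atom_weights:
        warnings.warn(
            f"element missing for atom {atom_name!r}; inferred {inferred!r} from the name",
            stacklevel=3,
        )
        return float(atom_weights[inferred.capitalize()])
    raise ValueError(f"cannot determine element/mass for atom {atom_name!r}")


def read_structure(path, ca_only: bool = False) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    First model only; for alternate locations the blank or 'A' altloc is
    kept.  Coordinates are converted Å → nm; masses come from the element
    (inferred from the atom name, with a warning, when the element column
    is absent).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"no models found in {path}")
    model = models[0]

    coords, names, elements, masses, serials, resnames, resids = (
        [], [], [], [], [], [], []
    )
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]  # first altloc
                elif atom.get_altloc() not in (" ", "", "A"):
                    continue
                name = atom.get_name()
                element = atom.element or ""
                coords.append(atom.coord * NM_PER_ANGSTROM)
                names.append(name)
                el = element.strip().capitalize() or _element_from_name(name)
                elements.append(el)
                masses.append(_mass_for_element(element, name))
                serials.append(atom.get_serial_number())
                resnames.append(residue.get_resname())
                resids.append(residue.get_id()[1])
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    st = Structure(
        coordinates=np.asarray(coords, dtype=float),
        names=names,
        elements=elements,
        masses=np.asarray(masses, dtype=float),
        serials=np.asarray(serials, dtype=int),
        residue_names=resnames,
        residue_ids=np.asarray(resids, dtype=int),
    )
    return st.ca_only() if ca_only else st


# ---------------------------------------------------------------------------
# charge tables
# ---------------------------------------------------------------------------

def read_charges(path, n_atoms: Optional[int] = None) -> np.ndarray:
    """Read a two-column `atom_index charge` table (whitespace or comma
    separated, ``#`` comments ignored), e.

    Rows may appear in any order; charges are returned sorted by atom
    index, which must form a contiguous 1..N (or 0..N−1) range with no
    duplicates.  ``n_atoms``, when given, must match.
    """
    df = pd.read_csv(
        path, sep=r"[,\s]+", engine="python", comment="#", header=None,
        names=["atom_index", "charge"],
    )
    if df.empty:
        raise ValueError(f"charge table {path} is empty")
    if df.isna().any().any():
        raise ValueError(f"charge table {path} has missing values")
    idx = df["atom_index"].to_numpy()
    if np.any(idx != idx.astype(int)):
        raise ValueError("atom indices must be integers")
    idx = idx.astype(int)
    if len(np.unique(idx)) != len(idx):
        dupes = sorted(set(i for i in idx if list(idx).count(i) > 1))
        raise ValueError(f"duplicate atom indices in charge table: {dupes}")
    order = np.argsort(idx)
    idx = idx[order]
    start = idx[0]
    if start not in (0, 1) or not np.array_equal(idx, np.arange(start, start + len(idx))):
        raise ValueError("atom indices must form a contiguous 0- or 1-based range")
    charges = df["charge"].to_numpy(dtype=float)[order]
    if n_atoms is not None and len(charges) != n_atoms:
        raise ValueError(
            f"charge table has {len(charges)} atoms but the structure has {n_atoms}"
        )
    return charges


# ---------------------------------------------------------------------------
# CSV time series dialects
# ---------------------------------------------------------------------------

#: Registered header → dialect name. Forces are per-atom tables, the rest
#: time series.
TIMESERIES_DIALECTS = {
    ("time_ns", "mux", "muy", "muz"): "dipole",
    ("time_ns", "theta"): "theta",
    ("time_ns", "rmsd_nm"): "rmsd",
    ("atom_index", "fx", "fy", "fz"): "force_vectors",
    ("atom_index", "fmag"): "force_magnitudes",
}

_DIALECT_HEADERS = {v: k for k, v in TIMESERIES_DIALECTS.items()}


def read_timeseries(path) -> tuple[str, pd.DataFrame]:
    """Read a CSV in one of the registered dialects.

    Returns ``(dialect, dataframe)``.  Unknown headers, NaN rows (named by
    row number) and non-monotone time columns are rejected — files are
    parsed per the documented dialect or refused, never silently misread.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")
    header = tuple(c.strip() for c in df.columns)
    if header not in TIMESERIES_DIALECTS:
        raise ValueError(
            f"unknown time-series header {header} in {path}; expected one of "
            f"{sorted(TIMESERIES_DIALECTS)}"
        )
    dialect = TIMESERIES_DIALECTS[header]
    df.columns = list(header)
    na_rows = df.index[df.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"NaN values in {path} at data row(s) {na_rows}")
    if "time_ns" in df.columns:
        t = df["time_ns"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"time column in {path} is not strictly increasing")
    return dialect, df


def write_timeseries(df: pd.DataFrame, path, dialect: str) -> None:
    """Write a dataframe in a registered dialect at full float precision."""
    header = _DIALECT_HEADERS.get(dialect)
    if header is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = set(header) - set(df.columns)
    if missing:
        raise ValueError(f"dataframe lacks columns {sorted(missing)} for dialect {dialect}")
    df.loc[:, list(header)].to_csv(path, index=False, float_format="%.17g")


def dipole_trajectory_to_frame(traj: DipoleTrajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_ns": traj.times,
            "mux": traj.dipoles[:, 0],
            "muy": traj.dipoles[:, 1],
            "muz": traj.dipoles[:, 2],
        }
    )


def dipole_trajectory_from_csv(path, replica_id: Optional[str] = None) -> DipoleTrajectory:
    dialect, df = read_timeseries(path)
    if dialect != "dipole":
        raise ValueError(f"{path} is a {dialect!r} file, not a dipole trajectory")
    return DipoleTrajectory(
        times=df["time_ns"].to_numpy(),
        dipoles=df[["mux", "muy", "muz"]].to_numpy(),
        replica_id=replica_id or str(path),
    )


def orientation_series_from_csv(path) -> OrientationSeries:
    dialect, df = read_timeseries(path)
    if dialect != "theta":
        raise ValueError(f"{path} is a {dialect!r} file, not a theta series")
    return OrientationSeries(
        times=df["time_ns"].to_numpy(), theta=df["theta"].to_numpy()
    )


# ---------------------------------------------------------------------------
# study configuration (YAML)
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "e0_vnm", "t0_ns", "sigma_ns", "direction", "n_replicas", "seed",
    "duration_ns", "base_duration_ns", "dt_ns", "engine", "system",
    "theta_k_coefficient", "theta_k_fixed", "theta_oscillation_amplitude",
    "theta_noise_sd", "theta_dt_ns", "damage", "preservation_threshold_nm",
    "final_window_ns", "plateau_delay_ns",
}


def _system_from_config(spec: dict) -> "RotorSystem":
    """Build the rotor either from a PDB + charge table or from explicit
    principal moments and a body-frame dipole."""
    from .rotor import RotorSystem, build_rotor

    kwargs = {
        k: spec[k] for k in ("temperature", "gamma", "label") if k in spec
    }
    if "pdb" in spec:
        st = read_structure(spec["pdb"])
        charges = read_charges(spec["charges"], n_atoms=len(st))
        return build_rotor(st.coordinates, charges, st.masses, **kwargs)
    return RotorSystem(
        principal_moments=np.asarray(spec["principal_moments"], float),
        dipole_body=np.asarray(spec["dipole_body"], float),
        charge=float(spec.get("charge", 0.0)),
        **kwargs,
    )


def load_study_config(path) -> StudyConfig:
    """Load a YAML study configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "damage" in raw and raw["damage"] is not None:
        raw["damage"] = DamageParams(**raw["damage"])
    if "direction" in raw:
        raw["direction"] = tuple(float(x) for x in raw["direction"])
    if raw.get("system") is not None:
        raw["system"] = _system_from_config(raw["system"])
    return StudyConfig(**raw)


def save_study_config(config: StudyConfig, path) -> None:
    data = {
        "e0_vnm": list(map(float, config.e0_vnm)),
        "t0_ns": list(map(float, config.t0_ns)),
        "sigma_ns": config.sigma_ns,
        "direction": list(map(float, config.direction)),
        "n_replicas": config.n_replicas,
        "seed": config.seed,
        "duration_ns": config.duration_ns,
        "base_duration_ns": config.base_duration_ns,
        "dt_ns": config.dt_ns,
        "engine": config.engine,
        "theta_k_coefficient": config.theta_k_coefficient,
        "theta_k_fixed": config.theta_k_fixed,
        "theta_oscillation_amplitude": config.theta_oscillation_amplitude,
        "theta_noise_sd": config.theta_noise_sd,
        "theta_dt_ns": config.theta_dt_ns,
        "damage": {
            "kappa": config.damage.kappa,
            "p": config.damage.p,
            "r_sat": config.damage.r_sat,
            "r0": config.damage.r0,
        },
        "preservation_threshold_nm": config.preservation_threshold_nm,
        "final_window_ns": config.final_window_ns,
        "plateau_delay_ns": config.plateau_delay_ns,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
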