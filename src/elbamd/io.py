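"""Text file formats: trajectory frames, checkpoints, PDB/XYZ export, configs.

The native frame format is a line-oriented text dialect with fixed column
order and units (nm, nm/ps, unit vectors, rad/ps).  Floats are written with
shortest round-trip precision, so read(write(frame)) is bit-identical.
Dipole columns are present exactly for the sites whose type carries a point
dipole.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .forcefield import SITE_ORDER
from .topology import SystemState, make_template

__all__ = ["FrameRecord", "write_frames", "read_frames", "state_to_frame",
           "frame_to_state", "export_pdb", "export_xyz", "load_run_config"]

_RESNAMES = {"water": "HOH", "DOPC": "DPC", "DSPC": "DSP", "DOPE": "DPE"}
_SITE_SHORT = {"water": "W", "choline": "CHO", "amine": "AMI",
               "phosphate": "PHO", "glycerol": "GLY", "ester": "EST",
               "tail": "TAL"}


@dataclass
class FrameRecord:
    step: int
    time: float
    box: np.ndarray
    mol: np.ndarray
    species: list       # per site
    site_name: list     # per site
    typ: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    u: np.ndarray = None
    omega: np.ndarray = None
    has_dipole: np.ndarray = None


class FrameFormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return repr(float(x))


def state_to_frame(state: SystemState, ff, step: int = 0) -> FrameRecord:
    tab = ff.tables()
    has_dip = tab["mu"][state.typ] > 0
    names = []
    for sp in state.mol_species:
        tpl = make_template(sp, ff)
        names.extend(_SITE_SHORT[t] for t in tpl.site_types)
    return FrameRecord(step=step, time=state.time, box=state.box.copy(),
                       mol=state.mol.copy(),
                       species=[state.mol_species[m] for m in state.mol],
                       site_name=names, typ=state.typ.copy(),
                       pos=state.pos.copy(), vel=state.vel.copy(),
                       u=state.u.copy(), omega=state.omega.copy(),
                       has_dipole=has_dip)


def frame_to_state(frame: FrameRecord) -> SystemState:
    mol_species = []
    seen = -1
    for m, sp in zip(frame.mol, frame.species):
        if m != seen:
            mol_species.append(sp)
            seen = m
    return SystemState(pos=frame.pos.copy(), vel=frame.vel.copy(),
                       u=frame.u.copy(), omega=frame.omega.copy(),
                       typ=frame.typ.copy(), mol=frame.mol.copy(),
                       leaflet=np.full(len(frame.mol), -1, np.int8),
                       box=frame.box.copy(), time=frame.time,
                       mol_species=mol_species)


def write_frames(path, frames, provenance: dict | None = None, mode="w"):
    """Write FrameRecords; ``provenance`` (version, parameter checksum,
    seed) is embedded in the header of the file."""
    with open(path, mode) as fh:
        if provenance and mode == "w":
            for k, v in provenance.items():
                fh.write(f"#% {k} {v}\n")
        for fr in frames:
            n = len(fr.pos)
            fh.write(f"#frame {fr.step} {_fmt(fr.time)} "
                     f"{_fmt(fr.box[0])} {_fmt(fr.box[1])} "
                     f"{_fmt(fr.box[2])} {n}\n")
            for i in range(n):
                cols = [str(int(fr.mol[i])), fr.species[i], fr.site_name[i],
                        str(int(fr.typ[i]))]
                cols += [_fmt(v) for v in fr.pos[i]]
                cols += [_fmt(v) for v in fr.vel[i]]
                if fr.has_dipole is not None and fr.has_dipole[i]:
                    cols += [_fmt(v) for v in fr.u[i]]
                    cols += [_fmt(v) for v in fr.omega[i]]
                fh.write(" ".join(cols) + "\n")


def read_frames(path):
    """Read the native trajectory format.  Raises FrameFormatError with a
    line number for malformed input and refuses truncated frames."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nline = 0
    while i < len(lines):
        line = lines[i]
        nline = i + 1
        i += 1
        if line.startswith("#%") or not line.strip():
            continue
        if not line.startswith("#frame"):
            raise FrameFormatError(f"line {nline}: expected frame header, "
                                   f"got {line.strip()!r}")
        try:
            _, step, time, bx, by, bz, n = line.split()
            step, n = int(step), int(n)
            box = np.array([float(bx), float(by), float(bz)])
        except ValueError:
            raise FrameFormatError(f"line {nline}: malformed frame header")
        if i + n > len(lines):
            raise FrameFormatError(
                f"truncated frame at line {nline}: expected {n} site lines, "
                f"found {len(lines) - i}")
        mol, species, names, typ = [], [], [], []
        pos, vel, u, om, hd = [], [], [], [], []
        for k in range(n):
            parts = lines[i + k].split()
            if len(parts) not in (10, 16):
                raise FrameFormatError(
                    f"line {i + k + 1}: expected 10 or 16 columns, "
                    f"got {len(parts)}")
            try:
                mol.append(int(parts[0]))
                species.append(parts[1])
                names.append(parts[2])
                typ.append(int(parts[3]))
                pos.append([float(x) for x in parts[4:7]])
                vel.append([float(x) for x in parts[7:10]])
                if len(parts) == 16:
                    u.append([float(x) for x in parts[10:13]])
                    om.append([float(x) for x in parts[13:16]])
                    hd.append(True)
                else:
                    u.append([0.0, 0.0, 0.0])
                    om.append([0.0, 0.0, 0.0])
                    hd.append(False)
            except ValueError:
                raise FrameFormatError(f"line {i + k + 1}: malformed site "
                                       "record") from None
        i += n
        frames.append(FrameRecord(
            step=step, time=float(time), box=box, mol=np.array(mol),
            species=species, site_name=names, typ=np.array(typ),
            pos=np.array(pos), vel=np.array(vel), u=np.array(u),
            omega=np.array(om), has_dipole=np.array(hd)))
    return frames


def export_pdb(path, frame: FrameRecord):
    """Lossy PDB export: CG sites as HETATM records (coordinates in
    Angstrom); dipole orientations are dropped."""
    if frame.has_dipole is not None and frame.has_dipole.any():
        warnings.warn("PDB export drops dipole orientations")
    with open(path, "w") as fh:
        b = frame.box * 10.0
        fh.write(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for i in range(len(frame.pos)):
            res = _RESNAMES.get(frame.species[i], "UNK")
            x, y, z = frame.pos[i] * 10.0
            fh.write(f"HETATM{i + 1:5d} {frame.site_name[i]:<4s}"
                     f"{res:>4s} {int(frame.mol[i]) % 10000:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
        fh.write("END\n")


def export_xyz(path, frame: FrameRecord):
    with open(path, "w") as fh:
        fh.write(f"{len(frame.pos)}\n")
        fh.write(f"box {frame.box[0]} {frame.box[1]} {frame.box[2]} "
                 f"time {frame.time}\n")
        for i in range(len(frame.pos)):
            x, y, z = frame.pos[i] * 10.0
            fh.write(f"{frame.site_name[i]} {x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_BUILD_KEYS = {"kind", "species", "n_lipids", "hydration", "area_per_lipid",
               "temperature", "n_waters", "density"}
_SIM_KEYS = {"dt", "temperature", "tau_t", "thermostat", "pressure", "tau_p",
             "kappa", "barostat", "skin", "nslab"}
_STAGE_KEYS = {"relax_steps", "nvt_ps", "npt_ps", "production_ps"}
_TOP_KEYS = {"build", "sim", "stages", "seed", "output", "log_stride",
             "traj_stride"}


def load_run_config(path) -> dict:
    """Load and schema-validate a YAML run configuration; unknown keys are
    rejected with a diagnostic."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    problems = [f"unknown top-level key {k!r}" for k in cfg
                if k not in _TOP_KEYS]
    for section, allowed in (("build", _BUILD_KEYS), ("sim", _SIM_KEYS),
                             ("stages", _STAGE_KEYS)):
        for k in (cfg.get(section) or {}):
            if k not in allowed:
                problems.append(f"unknown key {k!r} in section {section!r}")
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    return cfg
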