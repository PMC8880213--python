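"""Readers and writers for the text formats the pipeline touches.

Multi-frame (extended) XYZ carries paths and ensembles, with
``sigma=``/``energy=`` tokens on the comment line; floats are written
with 17 significant digits so every round trip is bit-exact.  A plain
whitespace/comma table carries per-atom charges and Lennard-Jones
parameters.  PDB reading is a minimal fixed-column coordinate import
(ATOM/HETATM records in file serial order, first altloc kept) — no
structure preparation of any kind.
"""

from __future__ import annotations

import io as _io
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .fep import FreeEnergyProfile
from .mep import StringPath

__all__ = [
    "write_xyz_frames",
    "read_xyz_frames",
    "write_path_xyz",
    "read_path_xyz",
    "read_pdb_coords",
    "read_parameter_table",
    "write_parameter_table",
    "write_profile_csv",
    "read_profile_csv",
]

_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _fmt(x: float) -> str:
    return _FMT % x


def write_xyz_frames(dest, frames):
    """Write multi-frame XYZ.

    ``frames`` is an iterable of ``(labels, coords, meta)`` where
    ``coords`` is a flattened (3N,) array and ``meta`` a dict whose
    items are serialized as ``key=value`` tokens on the comment line.
    """
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        for labels, coords, meta in frames:
            xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
            fh.write(f"{xyz.shape[0]}\n")
            fh.write(" ".join(f"{k}={_fmt(v)}" for k, v in meta.items()) + "\n")
            for lab, row in zip(labels, xyz):
                fh.write(f"{lab} {_fmt(row[0])} {_fmt(row[1])} {_fmt(row[2])}\n")
    finally:
        if own:
            fh.close()


def read_xyz_frames(source):
    """Read multi-frame XYZ into a list of ``(labels, coords, meta)``.

    ``coords`` come back flattened; numeric ``key=value`` comment tokens
    are parsed into the meta dict.  Atom-count mismatches raise
    :class:`ParseError` with the offending line number.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise ParseError(
                f"frame starting at line {i + 1} declares {n} atoms but the "
                f"file ends after {max(len(lines) - i - 2, 0)} coordinate lines"
            )
        meta = {}
        for tok in lines[i + 1].split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                try:
                    meta[key] = float(val)
                except ValueError:
                    meta[key] = val
        labels, coords = [], []
        for j in range(n):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"line {ln + 1}: expected 'label x y z', got {lines[ln]!r} "
                    f"(frame starting at line {i + 1} declares {n} atoms)"
                )
            labels.append(parts[0])
            try:
                coords.extend(float(p) for p in parts[1:4])
            except ValueError as exc:
                raise ParseError(f"line {ln + 1}: bad coordinate field") from exc
        frames.append((labels, np.array(coords), meta))
        i += 2 + n
    return frames


def write_path_xyz(dest, path: StringPath, labels=None):
    """Serialize a string path, one frame per image, active atoms first."""
    n_act = path.active.shape[1] // 3
    n_env = path.env.shape[1] // 3
    if labels is None:
        labels = [f"A{k}" for k in range(n_act)] + [f"E{k}" for k in range(n_env)]
    frames = []
    for k in range(path.n_images):
        meta = {"sigma": path.sigmas[k]}
        if path.energies is not None:
            meta["energy"] = path.energies[k]
        coords = np.concatenate([path.active[k], path.env[k]])
        frames.append((labels, coords, meta))
    write_xyz_frames(dest, frames)


def read_path_xyz(source, n_active: int, endpoint_policy="fixed") -> StringPath:
    """Rebuild a :class:`StringPath` from a multi-frame XYZ file."""
    frames = read_xyz_frames(source)
    if not frames:
        raise ParseError("no frames in path file")
    sigmas, active, env, energies = [], [], [], []
    for labels, coords, meta in frames:
        sigmas.append(meta.get("sigma", np.nan))
        active.append(coords[:3 * n_active])
        env.append(coords[3 * n_active:])
        energies.append(meta.get("energy", np.nan))
    energies = np.array(energies)
    return StringPath(np.array(sigmas), np.array(active), np.array(env),
                      energies=None if np.all(np.isnan(energies)) else energies,
                      endpoint_policy=endpoint_policy)


def read_pdb_coords(source):
    """Coordinates from ATOM/HETATM records of a PDB file.

    Positions in Å, file serial order preserved; for atoms with
    alternate locations only the first-seen altloc of each atom name /
    residue is kept (a warning is issued).  Unparseable coordinate
    fields raise :class:`ParseError` carrying the record text.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    labels, coords = [], []
    seen_alt = {}
    warned = False
    for line in lines:
        if not line.startswith(("ATOM", "HETATM")):
            continue
        altloc = line[16:17]
        if altloc not in (" ", ""):
            key = (line[17:27], line[12:16])  # residue id + atom name
            if key in seen_alt and seen_alt[key] != altloc:
                if not warned:
                    _warnings.warn(
                        "alternate locations present; keeping the first "
                        "altloc of each atom", stacklevel=2)
                    warned = True
                continue
            seen_alt[key] = altloc
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"bad coordinate fields in record: {line!r}") from exc
        labels.append(line[12:16].strip() or line[76:78].strip() or "X")
        coords.extend((x, y, z))
    return labels, np.array(coords)


def read_parameter_table(source) -> pd.DataFrame:
    """Per-atom parameter table: ``atom_id charge epsilon sigma``.

    Whitespace- or comma-delimited with a header row; charges in e,
    epsilon in kcal/mol, sigma in Å.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    # parse tokens as text, then convert with the exact float parser
    # (pandas' own float conversion is not round-trip exact)
    df = pd.read_csv(_io.StringIO(text), sep=r"[\s,]+", engine="python",
                     dtype=str)
    required = ["atom_id", "charge", "epsilon", "sigma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"parameter table is missing columns {missing}")
    df = df[required].copy()
    for col in ("charge", "epsilon", "sigma"):
        try:
            df[col] = [float(tok) for tok in df[col]]
        except ValueError as exc:
            raise ParseError(f"bad numeric value in column {col!r}") from exc
    return df


def write_parameter_table(dest, atom_ids, charges, epsilons, sigmas):
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        fh.write("atom_id charge epsilon sigma\n")
        for aid, q, e, s in zip(atom_ids, charges, epsilons, sigmas):
            fh.write(f"{aid} {_fmt(q)} {_fmt(e)} {_fmt(s)}\n")
    finally:
        if own:
            fh.close()


def write_profile_csv(profile: FreeEnergyProfile, dest):
    """CSV with columns sigma, E_qm_rel, F_int_cum, F, stderr at full
    float precision, rows ordered by sigma."""
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w") if own else dest
    try:
        fh.write("sigma,E_qm_rel,F_int_cum,F,stderr\n")
        for k in range(profile.sigma.size):
            fh.write(",".join(_fmt(v) for v in (
                profile.sigma[k], profile.E_qm_curve[k],
                profile.F_int_curve[k], profile.F[k], profile.stderr[k],
            )) + "\n")
    finally:
        if own:
            fh.close()


def read_profile_csv(source) -> FreeEnergyProfile:
    df = pd.read_csv(source, float_precision="round_trip")
    return FreeEnergyProfile(sigma=df["sigma"].to_numpy(),
                             F=df["F"].to_numpy(),
                             E_qm_curve=df["E_qm_rel"].to_numpy(),
                             F_int_curve=df["F_int_cum"].to_numpy(),
                             stderr=df["stderr"].to_numpy())
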