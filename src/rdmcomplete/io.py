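"""File formats: FCIDUMP integrals, the rdm-h5 container, sample-set text files.

* **FCIDUMP** — the de facto interchange format for molecular integrals:
  a ``&FCI`` namelist header followed by ``value i j k l`` records with
  1-based indices in chemists' notation ``(ij|kl)``; ``k = l = 0`` marks
  one-electron integrals and the all-zero record the core energy.  Records
  are expanded under the real-orbital 8-fold symmetry on read and converted
  to the physicists' ``<ik|jl>`` storage used internally.

* **rdm-h5 v1** — an HDF5 schema holding packed 2-RDM sectors under
  ``/rdm2/{aaaa,bbbb,abab}`` with ``n_orb``/``n_alpha``/``n_beta``/
  ``frozen_core`` attributes, optional spin 1-RDMs under ``/rdm1``,
  integrals under ``/ints`` and orbital rotations under ``/rotation``.

* **Sample sets** — plain-text two-column (row, col) index lists with a
  header carrying the matrix dimension and the sampling seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .coherence import OrbitalRotation
from .completion import SampleSet
from .rdm_model import (
    MolecularIntegrals,
    OneRDM,
    PackedSectorMatrix,
    SECTORS,
    TwoRDM,
    sector_dim,
)

__all__ = [
    "read_fcidump",
    "write_fcidump",
    "RdmContainer",
    "write_rdm_container",
    "read_rdm_container",
    "write_sample_set",
    "read_sample_set",
]

_SCHEMA = "rdm-h5"
_VERSION = 1


# ---------------------------------------------------------------------------
# FCIDUMP
# ---------------------------------------------------------------------------

def _chem_assign(chem: np.ndarray, i: int, j: int, k: int, l: int,
                 val: float) -> None:
    """Set (ij|kl) and its 8-fold symmetry partners."""
    for (a, b, c, d) in [(i, j, k, l), (j, i, k, l), (i, j, l, k),
                         (j, i, l, k), (k, l, i, j), (l, k, i, j),
                         (k, l, j, i), (l, k, j, i)]:
        chem[a, b, c, d] = val


def read_fcidump(path: str) -> MolecularIntegrals:
    """Parse an FCIDUMP file into active-space integrals.

    Integrals are expanded to full 4-index storage; malformed records and
    out-of-range or zero-based indices are rejected with their line number.
    Later duplicate records overwrite earlier ones (symmetry expansion is
    idempotent, so permuted duplicates are harmless).
    """
    with open(path) as fh:
        lines = fh.readlines()
    header = []
    body_start = None
    for ln, line in enumerate(lines):
        header.append(line)
        flat = line.upper().replace(" ", "")
        if "&END" in flat or flat.strip() == "/" or line.strip() == "/":
            body_start = ln + 1
            break
    if body_start is None:
        raise ValueError("FCIDUMP: no namelist terminator (&END or /) found")
    head = " ".join(header).upper().replace(",", " , ")
    norb = None
    for token in head.replace(",", " ").split():
        if token.startswith("NORB="):
            norb = int(token.split("=")[1])
    if norb is None:
        raise ValueError("FCIDUMP: NORB missing from the &FCI namelist")

    t = np.zeros((norb, norb))
    chem = np.zeros((norb, norb, norb, norb))
    e_core = 0.0
    for ln in range(body_start, len(lines)):
        line = lines[ln].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"FCIDUMP line {ln + 1}: expected "
                             f"'value i j k l', got {line!r}")
        try:
            val = float(parts[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"FCIDUMP line {ln + 1}: {exc}") from None
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise ValueError(
                    f"FCIDUMP line {ln + 1}: index {idx} outside "
                    f"[0, {norb}] (indices are 1-based)")
        if (i, j, k, l) == (0, 0, 0, 0):
            e_core = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise ValueError(
                    f"FCIDUMP line {ln + 1}: zero-based index in "
                    f"one-electron record {line!r}")
            t[i - 1, j - 1] = val
            t[j - 1, i - 1] = val
        elif 0 in (i, j, k, l):
            raise ValueError(
                f"FCIDUMP line {ln + 1}: zero-based index in "
                f"two-electron record {line!r}")
        else:
            _chem_assign(chem, i - 1, j - 1, k - 1, l - 1, val)
    return MolecularIntegrals(t, chem.transpose(0, 2, 1, 3), e_core)


def write_fcidump(path: str, ints: MolecularIntegrals,
                  n_elec: int = 0, ms2: int = 0) -> None:
    """Write integrals as FCIDUMP (unique records only)."""
    n = ints.n_orb
    chem = ints.v.transpose(0, 2, 1, 3)
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n},NELEC={n_elec},MS2={ms2},\n")
        fh.write(f" ORBSYM={','.join(['1'] * n)},\n ISYM=1,\n&END\n")
        seen = set()
        for i in range(n):
            for j in range(i + 1):
                for k in range(n):
                    for l in range(k + 1):
                        if (i, j) < (k, l):
                            continue
                        key = (i, j, k, l)
                        if key in seen or abs(chem[i, j, k, l]) < 1e-14:
                            continue
                        seen.add(key)
                        fh.write(f"{chem[i, j, k, l]:23.16e} "
                                 f"{i + 1} {j + 1} {k + 1} {l + 1}\n")
        for i in range(n):
            for j in range(i + 1):
                if abs(ints.t[i, j]) > 1e-14:
                    fh.write(f"{ints.t[i, j]:23.16e} {i + 1} {j + 1} 0 0\n")
        fh.write(f"{ints.e_core:23.16e} 0 0 0 0\n")


# ---------------------------------------------------------------------------
# rdm-h5 container
# ---------------------------------------------------------------------------

@dataclass
class RdmContainer:
    rdm2: TwoRDM | None = None
    rdm1: OneRDM | None = None
    ints: MolecularIntegrals | None = None
    rotation: OrbitalRotation | None = None


def write_rdm_container(path: str, rdm2: TwoRDM | None = None,
                        rdm1: OneRDM | None = None,
                        ints: MolecularIntegrals | None = None,
                        rotation: OrbitalRotation | None = None) -> None:
    """Write an rdm-h5 v1 container; absent components are simply omitted."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = _SCHEMA
        fh.attrs["version"] = _VERSION
        if rdm2 is not None:
            g = fh.create_group("rdm2")
            g.attrs["n_orb"] = rdm2.n_orb
            g.attrs["n_alpha"] = rdm2.n_alpha
            g.attrs["n_beta"] = rdm2.n_beta
            g.attrs["frozen_core"] = rdm2.frozen_core
            for label, sec in rdm2.sectors.items():
                g.create_dataset(label, data=sec.values)
        if rdm1 is not None:
            g = fh.create_group("rdm1")
            g.create_dataset("d_alpha", data=rdm1.d_alpha)
            g.create_dataset("d_beta", data=rdm1.d_beta)
        if ints is not None:
            g = fh.create_group("ints")
            g.create_dataset("t", data=ints.t)
            g.create_dataset("v", data=ints.v)
            g.attrs["e_core"] = ints.e_core
        if rotation is not None:
            g = fh.create_group("rotation")
            g.create_dataset("c_alpha", data=rotation.c_alpha)
            g.create_dataset("c_beta", data=rotation.c_beta)


def read_rdm_container(path: str) -> RdmContainer:
    """Read an rdm-h5 v1 container, validating schema and dimensions."""
    out = RdmContainer()
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("schema") != _SCHEMA:
            raise ValueError(f"{path}: not an {_SCHEMA} container")
        if int(fh.attrs.get("version", -1)) != _VERSION:
            raise ValueError(
                f"{path}: unsupported {_SCHEMA} version "
                f"{fh.attrs.get('version')} (expected {_VERSION})")
        if "rdm2" in fh:
            g = fh["rdm2"]
            n = int(g.attrs["n_orb"])
            sectors = {}
            for label in SECTORS:
                if label in g:
                    vals = np.asarray(g[label])
                    d = sector_dim(label, n)
                    if vals.shape != (d, d):
                        raise ValueError(
                            f"{path}: sector {label} has shape "
                            f"{vals.shape}, expected {(d, d)} for n_orb={n}")
                    sectors[label] = PackedSectorMatrix(label, n, vals)
            out.rdm2 = TwoRDM(sectors, n, int(g.attrs["n_alpha"]),
                              int(g.attrs["n_beta"]),
                              int(g.attrs.get("frozen_core", 0)))
        if "rdm1" in fh:
            out.rdm1 = OneRDM(np.asarray(fh["rdm1"]["d_alpha"]),
                              np.asarray(fh["rdm1"]["d_beta"]))
        if "ints" in fh:
            g = fh["ints"]
            out.ints = MolecularIntegrals(
                np.asarray(g["t"]), np.asarray(g["v"]),
                float(g.attrs["e_core"]))
        if "rotation" in fh:
            out.rotation = OrbitalRotation(
                np.asarray(fh["rotation"]["c_alpha"]),
                np.asarray(fh["rotation"]["c_beta"]))
    return out


# ---------------------------------------------------------------------------
# sample-set text files
# ---------------------------------------------------------------------------

def write_sample_set(path: str, s: SampleSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"# d={s.d} seed={s.seed}\n")
        for (i, j) in s.indices:
            fh.write(f"{i} {j}\n")


def read_sample_set(path: str) -> SampleSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# d="):
            raise ValueError(f"{path}: missing sample-set header")
        fields = dict(tok.split("=") for tok in header[2:].split())
        d = int(fields["d"])
        seed = None if fields.get("seed") in (None, "None") \
            else int(fields["seed"])
        idx = []
        for line in fh:
            if line.strip():
                i, j = (int(x) for x in line.split())
                idx.append((i, j))
    return SampleSet(d, tuple(idx), seed)
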