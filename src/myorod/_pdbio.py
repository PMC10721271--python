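"""Shared PDB input/output helpers (biotite-backed).

Models and trajectories are exchanged as (multi-model) PDB files with two
chains, A and B.  Calpha-only files carry one CA atom per residue; backbone
files carry N, CA, C per residue (sufficient for phi/psi dihedrals).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

_CHAIN_IDS = ("A", "B")


def _template(
    n_res: int, residue_numbers: np.ndarray, atom_names: tuple[str, ...]
) -> struc.AtomArray:
    n_atoms_per_res = len(atom_names)
    n_total = 2 * n_res * n_atoms_per_res
    arr = struc.AtomArray(n_total)
    chain = np.repeat(_CHAIN_IDS, n_res * n_atoms_per_res)
    res_id = np.tile(np.repeat(residue_numbers, n_atoms_per_res), 2)
    names = np.tile(atom_names, 2 * n_res)
    arr.chain_id = chain
    arr.res_id = res_id
    arr.res_name = np.full(n_total, "ALA")
    arr.atom_name = names
    arr.element = np.where(np.char.startswith(names.astype(str), "N"), "N", "C")
    arr.hetero = np.zeros(n_total, dtype=bool)
    return arr


def write_ca_frames(
    path,
    ca: np.ndarray,
    residue_numbers: np.ndarray,
    n_coords: np.ndarray | None = None,
    c_coords: np.ndarray | None = None,
) -> None:
    """Write frames of a two-chain model to a (multi-model) PDB file.

    ``ca`` (and optional ``n_coords``/``c_coords``) are shaped
    (n_frames, 2, n_residues, 3).  A single frame writes a plain PDB; more
    frames write MODEL/ENDMDL records.
    """
    ca = np.asarray(ca, dtype=float)
    n_frames, _, n_res, _ = ca.shape
    with_backbone = n_coords is not None and c_coords is not None
    atom_names = ("N", "CA", "C") if with_backbone else ("CA",)
    template = _template(n_res, np.asarray(residue_numbers), atom_names)

    per_res = len(atom_names)
    coord = np.empty((n_frames, 2 * n_res * per_res, 3))
    for fr in range(n_frames):
        parts = []
        for ch in range(2):
            if with_backbone:
                block = np.stack(
                    [n_coords[fr, ch], ca[fr, ch], c_coords[fr, ch]], axis=1
                )  # (n_res, 3 atoms, 3)
                parts.append(block.reshape(-1, 3))
            else:
                parts.append(ca[fr, ch])
        coord[fr] = np.concatenate(parts, axis=0)

    if n_frames == 1:
        template.coord = coord[0]
        structure = template
    else:
        structure = struc.from_template(template, coord)
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


def read_frames(path):
    """Read a (multi-model) two-chain PDB file.

    Returns ``(ca, residue_numbers, backbone)`` where ``ca`` is
    (n_frames, 2, n_residues, 3) and ``backbone`` is ``None`` for CA-only
    files or a dict with "N" and "C" arrays of the same shape.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    def per_chain(atom_name):
        chains = []
        numbers = None
        for cid in _CHAIN_IDS:
            mask = (stack.chain_id == cid) & (stack.atom_name == atom_name)
            if not mask.any():
                return None, None
            chains.append(stack.coord[:, mask, :])
            numbers = stack.res_id[mask]
        return np.stack(chains, axis=1), numbers

    ca, numbers = per_chain("CA")
    if ca is None:
        raise ValueError(f"no CA atoms in chains A/B of {path}")
    backbone = None
    n_arr, _ = per_chain("N")
    c_arr, _ = per_chain("C")
    if n_arr is not None and c_arr is not None:
        backbone = {"N": n_arr, "C": c_arr}
    return ca, np.asarray(numbers), backbone
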