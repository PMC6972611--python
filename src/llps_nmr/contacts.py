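"""Minimum proton-proton distances in explicit molecular clusters.

Compares NOE-derived interproton distances in the dense liquid phase with the
packing distances of the final crystal.  Input is a pre-expanded cluster of
molecules in Cartesian coordinates (extended XYZ with per-atom molecule id
and proton-group label); for each pair of proton groups the shortest
same-molecule (intramolecular) and different-molecule (intermolecular)
separations are found by an exhaustive all-pairs scan, which at cluster scale
(tens of molecules, a few protons each) is both the implementation and its
own gold standard.

Published crystal-contact distances for S- and racemic ibuprofen are shipped
as reference constants for the comparison report; they are literature values
from the deposited crystal structures, not computed here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["ProtonCloud", "min_group_distances", "read_xyz",
           "CRYSTAL_REFERENCE_ANGSTROM", "crystal_comparison_table"]

#: Literature minimum proton-proton distances (angstrom) in the ibuprofen
#: crystal structures (racemic and S forms), for comparison with dense-phase
#: NOE distances.  These are published reference values, not computed here.
CRYSTAL_REFERENCE_ANGSTROM = {
    ("a", "b"): {"rac": {"intra": 5.50, "inter": 2.44},
                 "S":   {"intra": 5.49, "inter": 2.58}},
    ("b", "c"): {"rac": {"intra": 6.61, "inter": 4.98},
                 "S":   {"intra": 6.21, "inter": 3.17}},
}


@dataclass
class ProtonCloud:
    """Proton coordinates of a molecular cluster.

    ``atoms`` holds one record per proton with columns ``mol_id`` (int),
    ``group`` (proton-group label, e.g. 'a'/'b'/'c') and ``x, y, z`` in
    angstrom.
    """

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"mol_id", "group", "x", "y", "z"} - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) == 0:
            raise ValueError("empty proton cloud")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def select(self, group: str) -> pd.DataFrame:
        sub = self.atoms[self.atoms["group"] == group]
        if len(sub) == 0:
            raise ValueError(f"proton group {group!r} absent from cloud")
        return sub


def read_xyz(source) -> ProtonCloud:
    """Read an extended XYZ file with per-atom ``mol_id`` and ``group`` fields.

    Format: atom count line, comment line, then one line per atom:
    ``element x y z mol_id group_label``.  ``source`` is a path or a string
    containing the file body.
    """
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(source)
    with handle:
        lines = [ln for ln in handle.read().splitlines()]
    if len(lines) < 3:
        raise ValueError("truncated XYZ file")
    n = int(lines[0].split()[0])
    rows = []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        if len(parts) < 6:
            raise ValueError(f"XYZ atom line needs 'element x y z mol_id group': {ln!r}")
        rows.append({"element": parts[0],
                     "x": float(parts[1]), "y": float(parts[2]), "z": float(parts[3]),
                     "mol_id": int(parts[4]), "group": parts[5]})
    if len(rows) != n:
        raise ValueError(f"XYZ header announces {n} atoms, found {len(rows)}")
    return ProtonCloud(atoms=pd.DataFrame(rows))


def min_group_distances(cloud: ProtonCloud, pair: tuple[str, str]):
    """Shortest intra- and intermolecular distances between two proton groups.

    Exhaustive over all proton pairs (label_1 in one group, label_2 in the
    other): ``intra_min`` is the minimum over same-molecule pairs, and
    ``inter_min`` the minimum over different-molecule pairs.  For a
    single-molecule cloud (or groups never co-occurring across molecules)
    ``inter_min`` is None.

    Returns
    -------
    (intra_min, inter_min) in angstrom; either may be None if no qualifying
    pair exists.
    """
    g1, g2 = pair
    a = cloud.select(g1)
    b = cloud.select(g2)
    d = cdist(a[["x", "y", "z"]].to_numpy(float), b[["x", "y", "z"]].to_numpy(float))
    same_mol = a["mol_id"].to_numpy()[:, None] == b["mol_id"].to_numpy()[None, :]
    if g1 == g2:
        # exclude self-pairs (zero distances on the diagonal of identical sets)
        same_atom = (a.index.to_numpy()[:, None] == b.index.to_numpy()[None, :])
        d = np.where(same_atom, np.inf, d)
    intra = d[same_mol]
    inter = d[~same_mol]
    intra_min = float(np.min(intra)) if intra.size and np.isfinite(np.min(intra)) else None
    inter_min = float(np.min(inter)) if inter.size else None
    return intra_min, inter_min


def crystal_comparison_table(noe_distances: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side report of NOE distances vs published crystal contacts.

    ``noe_distances`` is the tidy output of
    :func:`llps_nmr.noe.noe_distance_table` with dense-phase pair labels like
    ``'a*-b*'``.  Each row is matched to the corresponding crystal proton
    pair and annotated with the literature intra/intermolecular minima.
    """
    rows = []
    for _, rec in noe_distances.iterrows():
        key = tuple(p.rstrip("*") for p in rec["pair"].split("-"))
        ref = CRYSTAL_REFERENCE_ANGSTROM.get(key) or CRYSTAL_REFERENCE_ANGSTROM.get(key[::-1])
        row = {"pair": rec["pair"], "noe_distance_angstrom": rec["distance_angstrom"]}
        if ref is not None:
            for form in ("rac", "S"):
                row[f"crystal_{form}_inter_angstrom"] = ref[form]["inter"]
                row[f"crystal_{form}_intra_angstrom"] = ref[form]["intra"]
        rows.append(row)
    return pd.DataFrame(rows)
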