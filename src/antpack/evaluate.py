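"""Prediction accuracy against a reference structure.

Two standard side-chain metrics:

* chi1 / chi1+2 accuracy -- the percentage of residues whose chi1 (and,
  for "chi12", both chi1 and chi2) lie within a threshold (conventionally
  40 or 20 degrees) of the reference, allowing 180-degree flips of
  symmetric or commonly indistinguishable terminal groups (Asp, Glu, Phe,
  Tyr rings; Asn/Gln amides; His imidazole);
* side-chain heavy-atom RMSD -- per-residue RMSD over atoms from Cbeta
  outward, minimised over the allowed symmetric atom relabelings, with no
  superposition (the backbone is shared and fixed); the aggregate is the
  unweighted mean over residues (per-atom pooling available via a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import ATOM_SWAPS, CHI_PERIODICITY_180, n_chis
from .structure import ProteinStructure, Residue, measure_chis

__all__ = [
    "angular_difference",
    "chi_accuracy",
    "side_chain_rmsd",
    "EvalReport",
    "evaluate",
]


def angular_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles, in [0, 180]."""
    d = abs(float(a) - float(b)) % 360.0
    return min(d, 360.0 - d)


def _chi_difference(residue_type: str, k: int, pred: float, ref: float,
                    flip_table=CHI_PERIODICITY_180) -> float:
    """Delta chi_k honouring terminal-group 180-degree symmetry."""
    d = angular_difference(pred, ref)
    if (k + 1) in flip_table.get(residue_type, ()):
        d = min(d, angular_difference(pred, ref + 180.0))
    return d


def _paired_residues(pred: ProteinStructure, ref: ProteinStructure):
    if len(pred) != len(ref) or pred.sequence != ref.sequence:
        raise ValueError("prediction and reference disagree in sequence")
    return list(zip(pred.residues, ref.residues))


@dataclass
class EvalReport:
    """Side-chain accuracy summary over all eligible residues."""

    chi1_40: float
    chi1_20: float
    chi12_40: float
    chi12_20: float
    rmsd: float
    per_residue: list = field(default_factory=list)
    per_type: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "chi1_40": self.chi1_40,
            "chi1_20": self.chi1_20,
            "chi12_40": self.chi12_40,
            "chi12_20": self.chi12_20,
            "rmsd": self.rmsd,
            "per_residue": self.per_residue,
            "per_type": self.per_type,
            "excluded": self.excluded,
        }


def chi_accuracy(
    pred: ProteinStructure,
    ref: ProteinStructure,
    threshold: float,
    flip_table=CHI_PERIODICITY_180,
) -> tuple[float, float]:
    """(chi1%, chi12%) of residues within ``threshold`` degrees of the
    reference.  chi12 counts residues whose chi1 AND chi2 are both within
    the threshold; denominators are the residues possessing the respective
    angles (Ala/Gly excluded), and residues with incomplete reference side
    chains are skipped.
    """
    n1 = ok1 = n12 = ok12 = 0
    for p, r in _paired_residues(pred, ref):
        if n_chis(r.type) == 0:
            continue
        try:
            chis_p = measure_chis(p)
            chis_r = measure_chis(r)
        except KeyError:
            continue  # incomplete side chain in either structure
        d1 = _chi_difference(r.type, 0, chis_p[0], chis_r[0], flip_table)
        n1 += 1
        ok1 += d1 <= threshold
        if len(chis_r) >= 2:
            d2 = _chi_difference(r.type, 1, chis_p[1], chis_r[1], flip_table)
            n12 += 1
            ok12 += (d1 <= threshold) and (d2 <= threshold)
    pct1 = 100.0 * ok1 / n1 if n1 else 0.0
    pct12 = 100.0 * ok12 / n12 if n12 else 0.0
    return pct1, pct12


def _residue_rmsd(pred: Residue, ref: Residue, swap_table=ATOM_SWAPS) -> float | None:
    """Side-chain heavy-atom RMSD (Cbeta inclusive), minimum over allowed
    symmetric relabelings; None when the reference has no side-chain atoms."""
    ref_atoms = {a.name: a.position for a in ref.atoms if a.name not in ("N", "CA", "C", "O")}
    pred_atoms = {a.name: a.position for a in pred.atoms if a.name not in ("N", "CA", "C", "O")}
    if not ref_atoms:
        return None
    relabelings = [{}]
    for swaps in swap_table.get(ref.type, []):
        mapping = {}
        for x, y in swaps:
            mapping[x] = y
            mapping[y] = x
        relabelings.append(mapping)
    best = None
    for mapping in relabelings:
        sq = 0.0
        count = 0
        ok = True
        for name, rpos in ref_atoms.items():
            pname = mapping.get(name, name)
            if pname not in pred_atoms:
                ok = False
                break
            sq += float(np.sum((pred_atoms[pname] - rpos) ** 2))
            count += 1
        if not ok:
            continue
        rmsd = np.sqrt(sq / count)
        best = rmsd if best is None else min(best, rmsd)
    if best is None:
        raise ValueError(
            f"residue {ref.type}{ref.index}: atom sets do not match under any "
            "allowed relabeling"
        )
    return float(best)


def side_chain_rmsd(
    pred: ProteinStructure,
    ref: ProteinStructure,
    pooling: str = "per_residue",
    swap_table=ATOM_SWAPS,
) -> float:
    """Side-chain heavy-atom RMSD without superposition.

    ``pooling="per_residue"`` (default): unweighted mean over residues of
    the per-residue RMSD.  ``pooling="per_atom"``: a single RMSD pooled
    over all side-chain atoms.
    """
    if pooling not in ("per_residue", "per_atom"):
        raise ValueError("pooling must be 'per_residue' or 'per_atom'")
    values = []
    counts = []
    for p, r in _paired_residues(pred, ref):
        v = _residue_rmsd(p, r, swap_table)
        if v is None:
            continue
        natoms = sum(1 for a in r.atoms if a.name not in ("N", "CA", "C", "O"))
        values.append(v)
        counts.append(natoms)
    if not values:
        return 0.0
    if pooling == "per_atom":
        total_sq = sum(v * v * c for v, c in zip(values, counts))
        return float(np.sqrt(total_sq / sum(counts)))
    return float(np.mean(values))


def evaluate(
    pred: ProteinStructure,
    ref: ProteinStructure,
    thresholds=(20.0, 40.0),
) -> EvalReport:
    """Full accuracy report: chi metrics at 20/40 degrees, RMSD, and
    per-residue / per-type breakdowns."""
    lo, hi = sorted(thresholds)
    chi1_lo, chi12_lo = chi_accuracy(pred, ref, lo)
    chi1_hi, chi12_hi = chi_accuracy(pred, ref, hi)

    per_residue = []
    per_type: dict = {}
    excluded = []
    for p, r in _paired_residues(pred, ref):
        if n_chis(r.type) == 0:
            continue
        try:
            chis_p = measure_chis(p)
            chis_r = measure_chis(r)
        except KeyError:
            excluded.append(f"{r.type}{r.index}")
            continue
        deltas = [
            round(_chi_difference(r.type, k, cp, cr), 3)
            for k, (cp, cr) in enumerate(zip(chis_p, chis_r))
        ]
        v = _residue_rmsd(p, r)
        row = {"residue": f"{r.type}{r.index}", "delta_chi": deltas, "rmsd": v}
        per_residue.append(row)
        bucket = per_type.setdefault(r.type, {"n": 0, "rmsd": 0.0})
        bucket["n"] += 1
        bucket["rmsd"] += v if v is not None else 0.0
    for t, b in per_type.items():
        b["rmsd"] = round(b["rmsd"] / b["n"], 4) if b["n"] else 0.0

    return EvalReport(
        chi1_40=chi1_hi,
        chi1_20=chi1_lo,
        chi12_40=chi12_hi,
        chi12_20=chi12_lo,
        rmsd=side_chain_rmsd(pred, ref),
        per_residue=per_residue,
        per_type=per_type,
        excluded=excluded,
    )
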