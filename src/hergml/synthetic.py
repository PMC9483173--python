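"""Synthetic fixtures with the statistical structure of a curated hERG dataset.

Two generators:

* :func:`generate_descriptor_dataset` — a compounds x descriptors matrix
  with an exact class ratio (5:1 emulates the stricter potency threshold,
  1:1 the looser one), a few class-informative columns with a controllable
  standardized mean shift, and the rest pure noise.
* :func:`generate_activity_table` — a raw ChEMBL-style activity export over
  a fixed internal list of valid drug-like SMILES, with replicate IC50
  measurements in mixed units, a configurable fraction of high-spread
  (sigma > 2) outlier compounds, and deliberately injected records that
  violate each curation filter.

Activity values are generated on the pIC50 scale and back-converted to IC50
so the unit handling of the curation module is exercised.  The default band
mix (1/6 potent, 1/3 moderate, 1/2 inactive) reproduces the roughly 5:1
nonblocker:blocker ratio at pIC50 = 6 and 1:1 at pIC50 = 5 seen in curated
hERG data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    n_compounds: int = 600
    class_ratio: tuple[int, int] = (5, 1)  # INA : ACT
    n_informative: int = 5
    n_noise: int = 55
    effect_size: float = 1.5
    replicate_sd: float = 0.15
    max_replicates: int = 3
    fraction_outliers: float = 0.0
    band_probs: tuple[float, float, float] = (1 / 6, 1 / 3, 1 / 2)  # potent, moderate, inactive
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_informative + self.n_noise < 2:
            raise SyntheticError("need at least 2 descriptors in total")
        if self.effect_size < 0:
            raise SyntheticError("effect_size must be >= 0")
        if any(p <= 0 for p in self.class_ratio):
            raise SyntheticError("class_ratio parts must be positive")


def generate_descriptor_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Descriptor matrix with planted informative columns.

    Labels match ``class_ratio`` exactly (error if the total is not
    divisible).  Informative columns are Normal(+effect/2, 1) for ACT and
    Normal(-effect/2, 1) for INA; noise columns are Normal(0, 1).
    """
    ina_part, act_part = spec.class_ratio
    total_parts = ina_part + act_part
    if spec.n_compounds % total_parts:
        raise SyntheticError(
            f"{spec.n_compounds} compounds cannot realize an exact "
            f"{ina_part}:{act_part} ratio"
        )
    n_act = spec.n_compounds * act_part // total_parts
    n_ina = spec.n_compounds - n_act
    y = np.array(["ACT"] * n_act + ["INA"] * n_ina)

    rng = np.random.default_rng(spec.seed)
    informative = [f"inf_{i:02d}" for i in range(spec.n_informative)]
    noise = [f"noise_{i:02d}" for i in range(spec.n_noise)]
    shift = np.where(y == "ACT", spec.effect_size / 2.0, -spec.effect_size / 2.0)
    X_inf = rng.normal(0, 1, (spec.n_compounds, spec.n_informative)) + shift[:, None]
    X_noise = rng.normal(0, 1, (spec.n_compounds, spec.n_noise))
    X = pd.DataFrame(
        np.hstack([X_inf, X_noise]),
        columns=informative + noise,
        index=[f"cmp_{i:04d}" for i in range(spec.n_compounds)],
    )
    return X, y, informative


# ---------------------------------------------------------------------------
# SMILES fixture list: enumerated substituent variations on drug-like cores


_CORES = [
    "c1ccc({0})cc1",
    "c1ccc({0})nc1",
    "c1ccc2[nH]c({0})cc2c1",
    "C1CCN({0})CC1",
    "c1ccc(N{0})cc1",
    "O=C(c1ccccc1){0}",
]

_CORES_2 = [
    "c1cc({0})ccc1{1}",
    "c1cc({0})cnc1{1}",
    "O=C({0})Nc1ccc({1})cc1",
    "c1ccc(CN({0}){1})cc1",
    "c1cc({0})cc({1})c1O",
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCO", "CCN", "CO", "CN", "Cl", "F", "Br",
    "C(=O)O", "C(=O)NC", "C#N", "OC", "SC", "C(C)C", "CCc1ccccc1",
    "N1CCOCC1", "CC(=O)O", "CCCl",
]


def fixture_smiles(n: int) -> list[str]:
    """First n unique, RDKit-valid canonical SMILES from the template grids.

    Single-substituent variations come first, then two-substituent
    combinations; enumeration order is fixed, so the list is deterministic.
    """
    out: list[str] = []
    seen: set[str] = set()

    def push(smi: str) -> bool:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            return False
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            out.append(can)
        return len(out) == n

    for core, sub in itertools.product(_CORES, _SUBSTITUENTS):
        if push(core.format(sub)):
            return out
    for core, (s1, s2) in itertools.product(
        _CORES_2, itertools.product(_SUBSTITUENTS, repeat=2)
    ):
        if push(core.format(s1, s2)):
            return out
    raise SyntheticError(f"only {len(out)} fixture structures available, {n} requested")


_BANDS = {  # pIC50 ranges; margins keep replicate noise from flipping labels
    "potent": (6.2, 8.5),
    "moderate": (5.05, 5.95),
    "inactive": (2.5, 4.8),
}


def _structure_latent(smiles: list[str], effect_size: float, rng) -> np.ndarray:
    """Latent potency score coupled to computable 2D properties.

    The score is ``effect_size`` times a z-scored blend of lipophilicity
    (MolLogP) and polar surface area (negatively weighted), plus Gaussian
    noise — so at effect_size 0 the activity is pure noise, while at large
    effect sizes potency is a learnable function of structure, the situation
    a QSAR model assumes.  The noise scale (sd 0.5) is calibrated so that
    recovering the class from structure is about as hard here as recovering
    it from the descriptor-matrix generator at the same nominal effect size,
    where the shift is spread over several independent informative columns.
    """
    from rdkit.Chem import Crippen, rdMolDescriptors

    logp = np.array([Crippen.MolLogP(Chem.MolFromSmiles(s)) for s in smiles])
    tpsa = np.array([rdMolDescriptors.CalcTPSA(Chem.MolFromSmiles(s)) for s in smiles])

    def z(v):
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    signal = 0.7 * z(logp) - 0.3 * z(tpsa)
    return effect_size * z(signal) + rng.normal(0, 0.5, len(smiles))


def generate_activity_table(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChEMBL-style raw export plus a ground-truth manifest.

    Compounds are assigned to potency bands by the rank of a
    structure-coupled latent score (band proportions follow ``band_probs``
    exactly), then per-compound 1..max_replicates IC50 rows are emitted in
    mixed units around the band-drawn true pIC50; outlier compounds get
    replicates spread by sigma > 2.  One record violating each curation
    filter plus an inorganic salt, an unparseable SMILES, and a comment-only
    inactive are appended (flagged in the manifest as 'injected').
    """
    rng = np.random.default_rng(spec.seed)
    smiles = fixture_smiles(spec.n_compounds)
    latent = _structure_latent(smiles, spec.effect_size, rng)
    n = spec.n_compounds
    n_potent = int(round(spec.band_probs[0] * n))
    n_moderate = int(round(spec.band_probs[1] * n))
    order = np.argsort(-latent)  # most potent first
    bands = np.empty(n, dtype=object)
    bands[order[:n_potent]] = "potent"
    bands[order[n_potent:n_potent + n_moderate]] = "moderate"
    bands[order[n_potent + n_moderate:]] = "inactive"
    rows: list[dict] = []
    truth_rows: list[dict] = []
    units = ["nM", "uM", "M"]
    factors = {"nM": 1e-9, "uM": 1e-6, "M": 1.0}

    def base(smi, value, unit):
        return {
            "canonical_smiles": smi,
            "standard_type": "IC50",
            "standard_value": value,
            "standard_units": unit,
            "target_organism": "Homo sapiens",
            "assay_type": "B",
            "data_validity_comment": "",
            "activity_comment": "",
        }

    n_outliers = int(round(spec.fraction_outliers * spec.n_compounds))
    outlier_ids = set(rng.choice(spec.n_compounds, size=n_outliers, replace=False))
    for i, (smi, band) in enumerate(zip(smiles, bands)):
        lo, hi = _BANDS[band]
        true_p = float(rng.uniform(lo, hi))
        if i in outlier_ids:
            reps = [true_p - 3.0, true_p + 3.0]  # sample sd ~ 4.2 > 2
        else:
            n_rep = int(rng.integers(1, spec.max_replicates + 1))
            reps = list(true_p + rng.normal(0, spec.replicate_sd, n_rep))
        for p in reps:
            unit = units[int(rng.integers(len(units)))]
            ic50 = 10.0 ** (-p) / factors[unit]
            rows.append(base(smi, ic50, unit))
        truth_rows.append(
            {"smiles": smi, "true_pic50": true_p, "band": band, "outlier": i in outlier_ids}
        )

    injected = [
        ({**base("CCOC(=O)c1ccccc1", 500.0, "nM"), "target_organism": "Rattus norvegicus"},
         "non-human"),
        ({**base("CCOC(=O)c1ccccc1N", 500.0, "nM"), "assay_type": "F"}, "functional-assay"),
        ({**base("CCOC(=O)c1ccccc1O", 500.0, "nM"), "standard_type": "Ki"}, "wrong-type"),
        ({**base("CCOC(=O)c1ccccc1F", 500.0, "nM"),
          "data_validity_comment": "Outside typical range"}, "validity-warning"),
        (base("[Fe+2].[O-]S([O-])(=O)=O", 500.0, "nM"), "inorganic"),
        (base("not-a-smiles", 500.0, "nM"), "unparseable"),
        ({**base("Nc1ccc(S(N)(=O)=O)cc1", None, ""), "standard_value": None,
          "activity_comment": "Not Active"}, "comment-inactive"),
    ]
    for rec, tag in injected:
        rows.append(rec)
        truth_rows.append({"smiles": rec["canonical_smiles"], "true_pic50": np.nan,
                           "band": "injected:" + tag, "outlier": False})

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
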