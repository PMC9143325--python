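"""Molecular feature blocks: fingerprints, descriptors, imports, similarity.

A :class:`FeatureBlock` is a named ``n_molecules x d`` matrix, either binary
(fingerprint bits) or continuous (descriptors), with feature names and the
molecule ids its rows belong to. Blocks computed here, imported from
external tools, or concatenated from both feed every downstream stage
(preprocessing, modelling, applicability domain, alert mining).

Fingerprint families
--------------------
``MACCS``
    The 166 MDL public keys, via RDKit.
``PubChem``
    An 881-bit substructure fingerprint following the section layout of the
    public CACTVS/PubChem key set: exact element-count keys, ring-count keys
    derived from the smallest-set-of-smallest-rings, bonded element-pair
    keys, a curated SMARTS section, and a hashed substructure-path section
    standing in for the remaining keys. Width and determinism match the
    published layout; individual bit definitions in the last two sections
    are this package's own and are not bit-compatible with PaDEL/CACTVS.
``hashed``
    RDKit's path-based (Daylight-like) fingerprint at a configurable width,
    1024 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import LabeledDataset

logger = logging.getLogger("ditptox")

__all__ = [
    "FeatureBlock",
    "BasicProperties",
    "FeaturizationError",
    "compute_fingerprint",
    "compute_descriptors",
    "load_feature_table",
    "combine_blocks",
    "tanimoto_matrix",
    "basic_properties",
    "smarts_catalog_block",
]


class FeaturizationError(ValueError):
    pass


# --------------------------------------------------------------------------
# FeatureBlock container
# --------------------------------------------------------------------------


@dataclass
class FeatureBlock:
    """A named n x d feature matrix aligned to molecule ids.

    ``kind`` is ``binary``, ``continuous`` or ``mixed`` (after combining);
    for mixed blocks ``column_kinds`` records the kind per column.
    """

    name: str
    kind: str
    matrix: np.ndarray
    feature_names: list[str]
    row_ids: list[str]
    column_kinds: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise FeaturizationError("feature matrix must be 2-D")
        n, d = self.matrix.shape
        if len(self.feature_names) != d:
            raise FeaturizationError(
                f"{len(self.feature_names)} feature names for {d} columns"
            )
        if len(set(self.feature_names)) != d:
            raise FeaturizationError("feature names must be unique within a block")
        if len(self.row_ids) != n:
            raise FeaturizationError(f"{len(self.row_ids)} row ids for {n} rows")
        if self.kind not in ("binary", "continuous", "mixed"):
            raise FeaturizationError(f"unknown block kind {self.kind!r}")
        if self.kind == "binary":
            vals = self.matrix[np.isfinite(self.matrix)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise FeaturizationError(
                    f"binary block {self.name!r} contains values outside {{0,1}}"
                )
        if self.column_kinds is None:
            self.column_kinds = [
                self.kind if self.kind != "mixed" else "continuous"
            ] * d
        elif len(self.column_kinds) != d:
            raise FeaturizationError("column_kinds length mismatch")

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def reorder(self, row_ids: list[str]) -> "FeatureBlock":
        """Rows rearranged into the given id order (ids must all be present)."""
        index = {rid: i for i, rid in enumerate(self.row_ids)}
        missing = [rid for rid in row_ids if rid not in index]
        if missing:
            raise FeaturizationError(
                f"block {self.name!r} is missing molecule id(s) {missing[:5]}"
            )
        rows = [index[rid] for rid in row_ids]
        return FeatureBlock(
            self.name,
            self.kind,
            self.matrix[rows],
            list(self.feature_names),
            list(row_ids),
            column_kinds=list(self.column_kinds),
            meta=dict(self.meta),
        )

    def subset_rows(self, indices) -> "FeatureBlock":
        indices = list(indices)
        return FeatureBlock(
            self.name,
            self.kind,
            self.matrix[indices],
            list(self.feature_names),
            [self.row_ids[i] for i in indices],
            column_kinds=list(self.column_kinds),
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.row_ids, name="id"),
            columns=self.feature_names,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


# --------------------------------------------------------------------------
# RDKit helpers
# --------------------------------------------------------------------------


def _mols(ds: LabeledDataset):
    from rdkit import Chem

    mols = []
    for rec in ds.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise FeaturizationError(
                f"unparseable SMILES for molecule {rec.id!r}: {rec.smiles!r}"
            )
        mols.append(mol)
    return mols


# --------------------------------------------------------------------------
# PubChem-layout 881-bit fingerprint
# --------------------------------------------------------------------------

# Section 1 (115 keys): element-count thresholds of the public key set.
_ELEMENT_COUNT_KEYS: list[tuple[str, int]] = (
    [("H", t) for t in (4, 8, 16, 32)]
    + [("Li", t) for t in (1, 2)]
    + [("B", t) for t in (1, 2, 4)]
    + [("C", t) for t in (2, 4, 8, 16, 32)]
    + [("N", t) for t in (1, 2, 4, 8)]
    + [("O", t) for t in (1, 2, 4, 8, 16)]
    + [("F", t) for t in (1, 2, 4)]
    + [("Na", t) for t in (1, 2)]
    + [("Si", t) for t in (1, 2)]
    + [("P", t) for t in (1, 2, 4)]
    + [("S", t) for t in (1, 2, 4, 8)]
    + [("Cl", t) for t in (1, 2, 4, 8)]
    + [("K", t) for t in (1, 2)]
    + [("Br", t) for t in (1, 2, 4)]
    + [("I", t) for t in (1, 2, 4)]
    + [
        (el, 1)
        for el in (
            "Be Mg Al Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Kr Rb Sr Y "
            "Zr Nb Mo Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba Lu Hf Ta W Re Os Ir "
            "Pt Au Hg Tl Pb Bi La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Tc U"
        ).split()
    ]
)
assert len(_ELEMENT_COUNT_KEYS) == 115

# Section 2 (148 keys): ring-count thresholds by size and ring character.
# Count levels per ring size follow the public layout; the 7 character
# classes per level are: any, sat/arom carbon-only, sat/arom N-containing,
# sat/arom heteroatom-containing, unsat non-arom carbon-only, unsat
# non-arom N-containing, unsat non-arom heteroatom-containing.
_RING_LEVELS = {3: 2, 4: 2, 5: 5, 6: 5, 7: 2, 8: 2, 9: 1, 10: 1}
_RING_CLASSES = (
    "any",
    "satarom_carbon",
    "satarom_nitrogen",
    "satarom_hetero",
    "unsat_carbon",
    "unsat_nitrogen",
    "unsat_hetero",
)
_AROMATIC_RING_KEYS = [
    ("aromatic", t) for t in (1, 2, 3, 4)
] + [("heteroaromatic", t) for t in (1, 2, 3, 4)]

# Section 3 (64 keys): bonded element pairs.
_ELEMENT_PAIR_KEYS = [
    tuple(p.split("-"))
    for p in (
        "Li-H Li-Li B-H B-B B-C B-N B-O B-F B-Si B-P B-S B-Cl B-Br C-H C-C "
        "C-N C-O C-F C-Na C-Mg C-Al C-Si C-P C-S C-Cl C-As C-Se C-Br C-I "
        "N-H N-N N-O N-F N-Si N-P N-S N-Cl N-Br O-H O-O O-Mg O-Na O-Al "
        "O-Si O-P O-K F-P F-S Mg-H Si-H Si-Si Si-Cl P-H P-P As-H As-As "
        "S-H S-S S-Cl Cl-H Sn-H Pb-H Se-H Se-Se"
    ).split()
]
assert len(_ELEMENT_PAIR_KEYS) == 64

# Section 4: curated substructure SMARTS (functional groups, hetero
# environments, common scaffolds). These are this package's own keys.
_PUBCHEM_SMARTS: list[str] = [
    # carbonyl / carboxyl family
    "[CX3]=[OX1]", "[CX3](=O)[OX2H1]", "[CX3](=O)[OX1-]", "[CX3](=O)[OX2][#6]",
    "[CX3](=O)[NX3]", "[CX3](=O)[NX3H2]", "[CX3](=O)[NX3H1][#6]",
    "[CX3H1]=O", "[CX3](=O)[#6]", "O=C([#6])[#6]", "[NX3][CX3](=O)[NX3]",
    "O=C[OX2]C=O", "[CX3](=O)Cl", "[CX3](=S)[NX3]", "C(=O)C(=O)",
    # nitrogen groups
    "[NX3;H2][#6]", "[NX3;H1]([#6])[#6]", "[NX3]([#6])([#6])[#6]",
    "[NX4+]", "[NX3][NX3]", "[NX2]=[NX2]", "[NX1]#[CX2]", "[NX2]=[CX3]",
    "[NX3][OX2H]", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "[NX2]=[OX1]", "[NX3H1]C=N", "N=C=O", "N=C=S", "[NX3][CX2]#[NX1]",
    "C=NO", "[#6]N=N[#6]", "[NX3H2][NX3H1]",
    # oxygen groups
    "[OX2H][#6;!$([CX3]=O)]", "[OX2H][cX3]", "[OX2]([#6])[#6]",
    "[OX2H][CX4]", "c[OX2][#6]", "[OX2][OX2]", "[OX2H][CX3]=[CX3]",
    # sulfur groups
    "[SX2H]", "[SX2]([#6])[#6]", "[SX3]=[OX1]",
    "[SX4](=[OX1])(=[OX1])", "[SX4](=O)(=O)[NX3]", "[SX4](=O)(=O)[OX2H]",
    "[SX4](=O)(=O)[#6]", "[#6][SX2][SX2][#6]", "c[SX2][#6]", "S=C",
    # phosphorus
    "[PX4](=[OX1])", "[PX4](=O)([OX2])[OX2]", "[PX3]",
    # halogen environments
    "[#6]F", "[#6]Cl", "[#6]Br", "[#6]I", "[CX4](F)(F)F", "c-F", "c-Cl",
    "c-Br", "c-I", "[CX4](Cl)Cl",
    # hydrocarbon environments
    "[CX4H3][#6]", "[CX4H2]([#6])[#6]", "[CX4H1]([#6])([#6])[#6]",
    "[CX4]([#6])([#6])([#6])[#6]", "[CX3]=[CX3]", "[CX2]#[CX2]",
    "[CX3H2]=[CX3H1]", "C=C-C=C", "[cX3H1]", "c:c:c",
    # aromatic carbocycles and substitution
    "c1ccccc1", "c1ccccc1[#6]", "c1ccccc1[OX2H]", "c1ccccc1[NX3]",
    "c1ccccc1C=O", "c1ccc2ccccc2c1", "c1ccccc1-c1ccccc1",
    "Cc1ccccc1C", "Cc1ccc(C)cc1", "Cc1cccc(C)c1",
    # nitrogen heteroaromatics
    "c1ccncc1", "c1ccnc(c1)", "n1ccccc1", "c1cc[nH]c1", "c1cnc[nH]1",
    "c1cncnc1", "c1ccc2[nH]ccc2c1", "c1ccc2ncccc2c1", "c1ccc2nc[nH]c2c1",
    "n1cnc2c1cncn2", "c1nnc[nH]1", "c1cn[nH]c1", "n1ccnc1", "c1nccs1",
    "c1ncco1",
    # oxygen / sulfur heteroaromatics and saturated heterocycles
    "c1ccoc1", "c1ccsc1", "C1CCOC1", "C1CCOCC1", "C1CCNC1", "C1CCNCC1",
    "C1CCCNC1", "N1CCOCC1", "N1CCNCC1", "C1CO1", "C1CN1", "O=C1CCN1",
    "O=C1CCCN1", "O=C1NC(=O)NC(=O)C1", "C1CCCCC1", "C1CCCC1", "C1CC1",
    "C1CCC1", "C1CCCCCC1",
    # pharmacophore-ish combinations
    "[NX3][CX4][CX3](=O)", "[OX2H][CX4][NX3]", "c1ccccc1[CX4][NX3]",
    "[NX3][CX4][CX4][OX2H]", "c1ccccc1S(=O)(=O)N", "[#6]C(=O)Nc1ccccc1",
    "[OX2H]c1ccccc1[CX3]=O", "[NX3H2]c1ccccc1", "O=C(N)c1ccccc1",
    "[#8]=[#6]1[#6][#6][#7]1",  # beta-lactam carbonyl ring
]

_PUBCHEM_WIDTH = 881


def _element_counts(mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
    return counts


def _ring_profile(mol):
    """Classify each SSSR ring by size, saturation/aromaticity and content."""
    from rdkit import Chem

    ri = mol.GetRingInfo()
    profiles = []
    for atom_ids, bond_ids in zip(ri.AtomRings(), ri.BondRings()):
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        bonds = [mol.GetBondWithIdx(i) for i in bond_ids]
        aromatic = all(b.GetIsAromatic() for b in bonds)
        saturated = all(
            b.GetBondType() == Chem.BondType.SINGLE for b in bonds
        )
        has_n = any(a.GetSymbol() == "N" for a in atoms)
        hetero = any(a.GetSymbol() != "C" for a in atoms)
        profiles.append(
            {
                "size": len(atom_ids),
                "aromatic": aromatic,
                "satarom": aromatic or saturated,
                "unsat": not aromatic and not saturated,
                "nitrogen": has_n,
                "hetero": hetero,
                "carbon_only": not hetero,
            }
        )
    return profiles


def _ring_bits(mol) -> tuple[np.ndarray, list[str]]:
    profiles = _ring_profile(mol)
    bits: list[int] = []
    names: list[str] = []

    def count(pred) -> int:
        return sum(1 for p in profiles if pred(p))

    for size, levels in _RING_LEVELS.items():
        per_class = {
            "any": count(lambda p, s=size: p["size"] == s),
            "satarom_carbon": count(
                lambda p, s=size: p["size"] == s and p["satarom"] and p["carbon_only"]
            ),
            "satarom_nitrogen": count(
                lambda p, s=size: p["size"] == s and p["satarom"] and p["nitrogen"]
            ),
            "satarom_hetero": count(
                lambda p, s=size: p["size"] == s and p["satarom"] and p["hetero"]
            ),
            "unsat_carbon": count(
                lambda p, s=size: p["size"] == s and p["unsat"] and p["carbon_only"]
            ),
            "unsat_nitrogen": count(
                lambda p, s=size: p["size"] == s and p["unsat"] and p["nitrogen"]
            ),
            "unsat_hetero": count(
                lambda p, s=size: p["size"] == s and p["unsat"] and p["hetero"]
            ),
        }
        for level in range(1, levels + 1):
            for cls in _RING_CLASSES:
                bits.append(1 if per_class[cls] >= level else 0)
                names.append(f"ring:size{size}:{cls}>={level}")

    n_arom = count(lambda p: p["aromatic"])
    n_het_arom = count(lambda p: p["aromatic"] and p["hetero"])
    for label, threshold in _AROMATIC_RING_KEYS:
        n = n_arom if label == "aromatic" else n_het_arom
        bits.append(1 if n >= threshold else 0)
        names.append(f"ring:{label}>={threshold}")
    return np.array(bits, dtype=float), names


def _pubchem_fingerprint_names() -> list[str]:
    names = [f"el:{el}>={t}" for el, t in _ELEMENT_COUNT_KEYS]
    # ring names depend only on the layout, not the molecule
    dummy_bits, ring_names = _ring_bits(_benzene())
    names += ring_names
    names += [f"pair:{a}-{b}" for a, b in _ELEMENT_PAIR_KEYS]
    names += [f"smarts:{s}" for s in _PUBCHEM_SMARTS]
    n_hash = _PUBCHEM_WIDTH - len(names)
    names += [f"hash:{k}" for k in range(n_hash)]
    return names


def _benzene():
    from rdkit import Chem

    return Chem.MolFromSmiles("c1ccccc1")


def _pubchem_fingerprint(mol) -> np.ndarray:
    from rdkit import Chem

    counts = _element_counts(mol)
    bits = [1.0 if counts.get(el, 0) >= t else 0.0 for el, t in _ELEMENT_COUNT_KEYS]

    ring, _ = _ring_bits(mol)
    bits.extend(ring.tolist())

    present_pairs = set()
    for bond in mol.GetBonds():
        a = bond.GetBeginAtom().GetSymbol()
        b = bond.GetEndAtom().GetSymbol()
        present_pairs.add(frozenset((a, b)))
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() > 0:
            present_pairs.add(frozenset((atom.GetSymbol(), "H")))
    for a, b in _ELEMENT_PAIR_KEYS:
        bits.append(1.0 if frozenset((a, b)) in present_pairs else 0.0)

    for smarts in _PUBCHEM_SMARTS:
        patt = _smarts_cache(smarts)
        bits.append(1.0 if mol.HasSubstructMatch(patt) else 0.0)

    n_hash = _PUBCHEM_WIDTH - len(bits)
    hashed = Chem.PatternFingerprint(mol, fpSize=n_hash)
    bits.extend(float(hashed.GetBit(i)) for i in range(n_hash))
    out = np.array(bits, dtype=float)
    assert out.size == _PUBCHEM_WIDTH
    return out


_SMARTS_CACHE: dict[str, object] = {}


def _smarts_cache(smarts: str):
    from rdkit import Chem

    patt = _SMARTS_CACHE.get(smarts)
    if patt is None:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise FeaturizationError(f"invalid SMARTS pattern {smarts!r}")
        _SMARTS_CACHE[smarts] = patt
    return patt


# --------------------------------------------------------------------------
# Public featurizers
# --------------------------------------------------------------------------


def compute_fingerprint(
    ds: LabeledDataset, family: str = "PubChem", **params
) -> FeatureBlock:
    """Binary fingerprint block for every molecule in the dataset.

    ``family`` is ``MACCS`` (166 bits), ``PubChem`` (881 bits) or ``hashed``
    (path-based, ``width`` parameter, default 1024 — the stand-in for the
    CDK/ExtFP dimensionality). Output is deterministic for fixed input.
    """
    mols = _mols(ds)
    if family == "MACCS":
        from rdkit.Chem import MACCSkeys

        rows = []
        for mol in mols:
            fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
            rows.append([float(fp.GetBit(i)) for i in range(1, 167)])
        names = [f"maccs:{i}" for i in range(1, 167)]
        matrix = np.array(rows)
    elif family == "PubChem":
        matrix = np.vstack([_pubchem_fingerprint(m) for m in mols])
        names = _pubchem_fingerprint_names()
    elif family == "hashed":
        from rdkit import Chem

        width = int(params.get("width", 1024))
        rows = []
        for mol in mols:
            fp = Chem.RDKFingerprint(mol, fpSize=width)
            rows.append([float(fp.GetBit(i)) for i in range(width)])
        names = [f"path:{i}" for i in range(width)]
        matrix = np.array(rows)
    else:
        raise FeaturizationError(
            f"unknown fingerprint family {family!r} "
            "(expected MACCS, PubChem or hashed)"
        )
    return FeatureBlock(family, "binary", matrix, names, ds.ids)


# The 13 commonly used descriptors. Two of the original thirteen come from
# proprietary software; open substitutes are used (and logged) by default:
# ESOL log-solubility for "molecular solubility" and Crippen logP for the
# apparent partition coefficient at pH 7.4.
_13MD_NAMES = [
    "MolSolubility",
    "MW",
    "ALogP",
    "LogD74",
    "nHBD",
    "nNO",
    "nHBA",
    "nRot",
    "nRing",
    "nAromRing",
    "MolSurfaceArea",
    "PSA",
    "FracPSA",
]


def _esol_log_solubility(mol) -> float:
    """Delaney ESOL estimate: logS from logP, MW, rotatable bonds and
    aromatic proportion."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = arom / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _descriptors_13md(mol, drop_proprietary: bool) -> dict[str, float]:
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    asa = Descriptors.LabuteASA(mol)
    tpsa = Descriptors.TPSA(mol)
    vals = {
        "MW": Descriptors.MolWt(mol),
        "ALogP": Crippen.MolLogP(mol),
        "nHBD": float(Lipinski.NumHDonors(mol)),
        "nNO": float(Lipinski.NOCount(mol)),
        "nHBA": float(Lipinski.NumHAcceptors(mol)),
        "nRot": float(Lipinski.NumRotatableBonds(mol)),
        "nRing": float(Descriptors.RingCount(mol)),
        "nAromRing": float(Descriptors.NumAromaticRings(mol)),
        "MolSurfaceArea": asa,
        "PSA": tpsa,
        "FracPSA": tpsa / asa if asa > 0 else 0.0,
    }
    if not drop_proprietary:
        vals["MolSolubility"] = _esol_log_solubility(mol)
        vals["LogD74"] = Crippen.MolLogP(mol)
    return vals


def compute_descriptors(
    ds: LabeledDataset, set_name: str = "RDMD", drop_proprietary: bool = False
) -> FeatureBlock:
    """Continuous descriptor block.

    ``13MD`` is the fixed 13-property set (solubility and logD backed by
    open estimators unless ``drop_proprietary``); ``RDMD`` is the full
    RDKit descriptor list, with names recorded from the provider. Provider
    failures on a molecule yield non-finite values, flagged in
    ``block.meta['failed_rows']`` and removed later by preprocessing.
    """
    mols = _mols(ds)
    failed: list[str] = []
    if set_name == "13MD":
        if not drop_proprietary:
            logger.info(
                "13MD: MolSolubility estimated by ESOL and LogD74 by Crippen "
                "logP (open substitutes for proprietary descriptors)"
            )
        names = [
            n for n in _13MD_NAMES
            if not (drop_proprietary and n in ("MolSolubility", "LogD74"))
        ]
        if drop_proprietary:
            warnings.warn(
                "13MD without proprietary substitutes has 11 descriptors",
                stacklevel=2,
            )
        rows = []
        for rec, mol in zip(ds.records, mols):
            try:
                vals = _descriptors_13md(mol, drop_proprietary)
                rows.append([vals[n] for n in names])
            except Exception:  # provider failure: flag, keep row
                failed.append(rec.id)
                rows.append([np.nan] * len(names))
        matrix = np.array(rows)
    elif set_name == "RDMD":
        from rdkit.Chem import Descriptors

        names = None
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rec, mol in zip(ds.records, mols):
                try:
                    vals = Descriptors.CalcMolDescriptors(mol)
                except Exception:
                    failed.append(rec.id)
                    vals = {}
                if names is None:
                    names = sorted(vals) if vals else None
                rows.append(vals)
        if names is None:
            raise FeaturizationError("descriptor provider failed on every molecule")
        matrix = np.array(
            [
                [float(r.get(n, np.nan)) if r else np.nan for n in names]
                for r in rows
            ]
        )
    else:
        raise FeaturizationError(
            f"unknown descriptor set {set_name!r} (expected 13MD or RDMD)"
        )
    block = FeatureBlock(set_name, "continuous", matrix, list(names), ds.ids)
    block.meta["failed_rows"] = failed
    return block


def smarts_catalog_block(
    ds: LabeledDataset, smarts_list: list[str], name: str = "SMARTS"
) -> FeatureBlock:
    """Binary block from a user-supplied SMARTS catalogue (one bit per
    pattern). This is the import path for externally defined fragment key
    sets that are not reimplemented bit-exactly."""
    mols = _mols(ds)
    patts = [_smarts_cache(s) for s in smarts_list]
    matrix = np.array(
        [[1.0 if m.HasSubstructMatch(p) else 0.0 for p in patts] for m in mols]
    )
    return FeatureBlock(name, "binary", matrix, list(smarts_list), ds.ids)


def load_feature_table(
    path, kind: str, name: str, row_ids: list[str] | None = None,
    id_column: str = "id",
) -> FeatureBlock:
    """Import an externally computed feature table (CSV, one row per
    molecule, id column + numeric columns). Rows are reordered to the
    dataset's id order when ``row_ids`` is given."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        # fall back: first column is the id
        df = df.rename(columns={df.columns[0]: id_column})
    ids = df[id_column].astype(str).tolist()
    feats = df.drop(columns=[id_column])
    matrix = feats.to_numpy(dtype=float)
    if kind == "binary":
        bad = ~np.isin(matrix, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FeaturizationError(
                f"binary table {name!r} contains non-binary value "
                f"{matrix[i, j]!r} at row id {ids[i]!r}, column "
                f"{feats.columns[j]!r}"
            )
    block = FeatureBlock(name, kind, matrix, feats.columns.tolist(), ids)
    if row_ids is not None:
        block = block.reorder(list(row_ids))
    return block


def combine_blocks(blocks: list[FeatureBlock]) -> FeatureBlock:
    """Column-wise concatenation of aligned blocks, names prefixed with the
    block name. Rows are aligned by molecule id to the first block's order."""
    if not blocks:
        raise FeaturizationError("no blocks to combine")
    if len(blocks) == 1:
        return blocks[0]
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise FeaturizationError(f"duplicate block names in {names}")
    ref_ids = blocks[0].row_ids
    aligned = [blocks[0]] + [b.reorder(ref_ids) for b in blocks[1:]]
    matrix = np.hstack([b.matrix for b in aligned])
    feature_names = [
        f"{b.name}:{f}" for b in aligned for f in b.feature_names
    ]
    column_kinds = [ck for b in aligned for ck in b.column_kinds]
    kinds = set(column_kinds)
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    return FeatureBlock(
        " + ".join(names), kind, matrix, feature_names, list(ref_ids),
        column_kinds=column_kinds,
    )


def tanimoto_matrix(fp: FeatureBlock) -> tuple[np.ndarray, float]:
    """Pairwise Tanimoto similarity |a AND b| / |a OR b| of a binary block.

    Returns the n x n matrix and the mean of its off-diagonal entries. A
    pair of all-zero fingerprints is defined as maximally similar (1).
    """
    if fp.kind != "binary":
        raise FeaturizationError("tanimoto_matrix needs a binary block")
    x = fp.matrix.astype(bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    n = sim.shape[0]
    if n > 1:
        off = sim[~np.eye(n, dtype=bool)]
        mean_off = float(off.mean())
    else:
        mean_off = float("nan")
    return sim, mean_off


@dataclass(frozen=True)
class BasicProperties:
    """Six key physicochemical properties used for chemical-space summaries."""

    MW: float
    AlogP: float
    nHBA: int
    nHBD: int
    nRot: int
    nRing: int

    def as_dict(self) -> dict:
        return {
            "MW": self.MW,
            "AlogP": self.AlogP,
            "nHBA": self.nHBA,
            "nHBD": self.nHBD,
            "nRot": self.nRot,
            "nRing": self.nRing,
        }


def basic_properties(ds: LabeledDataset) -> list[BasicProperties]:
    """MW, AlogP (Crippen), H-bond acceptor/donor, rotatable-bond and ring
    counts per molecule, for chemical-space plots and summary export."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    out = []
    for mol in _mols(ds):
        out.append(
            BasicProperties(
                MW=float(Descriptors.MolWt(mol)),
                AlogP=float(Crippen.MolLogP(mol)),
                nHBA=int(Lipinski.NumHAcceptors(mol)),
                nHBD=int(Lipinski.NumHDonors(mol)),
                nRot=int(Lipinski.NumRotatableBonds(mol)),
                nRing=int(Descriptors.RingCount(mol)),
            )
        )
    return out
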