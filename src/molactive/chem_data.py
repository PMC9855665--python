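"""Compound tables: I/O, cleaning workflow, task assembly and splits.

The cleaning workflow mirrors the standard preprocessing used to build
stage-wise drug-likeness corpora: an organic filter, an element whitelist,
largest-fragment extraction, charge standardization, aromatic perception,
canonicalization and duplicate removal — applied in that order, with a
per-step removal tally so input/output counts always reconcile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Allowed elements; anything else causes removal at the element filter.
ALLOWED_ELEMENTS = frozenset({"C", "H", "O", "N", "P", "S", "Cl", "Br", "I", "F"})

#: Cleaning step names, in execution order.
CLEANING_STEPS = (
    "organic_filter",
    "element_filter",
    "connectivity",
    "standardizer",
    "aromatizer",
    "canonicalize",
    "duplicate_filter",
)


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: a SMILES string with an optional binary label."""

    smiles: str
    label: int | None = None
    id: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class CleaningReport:
    """Per-step removal tally for one cleaning run.

    Invariant: ``n_input == n_output + sum(removed_per_step) + parse_failures``.
    """

    n_input: int
    removed_per_step: dict[str, int]
    parse_failures: int
    n_output: int

    def __post_init__(self) -> None:
        if set(self.removed_per_step) != set(CLEANING_STEPS):
            raise ValueError("removed_per_step must cover exactly the cleaning steps")
        total = self.n_output + sum(self.removed_per_step.values()) + self.parse_failures
        if total != self.n_input:
            raise ValueError(
                f"cleaning counts do not reconcile: input {self.n_input}, "
                f"accounted {total}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "removed_per_step": self.removed_per_step,
                "parse_failures": self.parse_failures,
                "n_output": self.n_output,
            },
            indent=2,
        )


@dataclass(frozen=True)
class DatasetSplit:
    """A held-out test set plus five independent 4:1 train/validation folds."""

    test_indices: tuple[int, ...]
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    seed: int


_UNCHARGER = rdMolStandardize.Uncharger(canonicalOrder=True)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest fragment by heavy atoms, then total atoms, then canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(frag: Chem.Mol):
        heavy = frag.GetNumHeavyAtoms()
        total = sum(a.GetTotalNumHs() for a in frag.GetAtoms()) + heavy
        smi = Chem.MolToSmiles(frag)
        # maximize heavy, then total, then take lexicographically smallest SMILES
        return (-heavy, -total, smi)

    return min(frags, key=key)


def clean_compounds(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], CleaningReport]:
    """Run the 7-step cleaning workflow, tallying removals per step.

    Steps, in order: organic filter (>=1 carbon), element whitelist,
    largest-fragment extraction, charge standardization, aromatic
    perception, canonical SMILES emission, first-occurrence duplicate
    removal. Unparseable SMILES are tallied as ``parse_failures`` and never
    raise per-record.
    """
    removed = {step: 0 for step in CLEANING_STEPS}
    parse_failures = 0
    out: list[CompoundRecord] = []
    seen: set[str] = set()

    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            parse_failures += 1
            continue
        # 1. organic filter: at least one carbon atom
        if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
            removed["organic_filter"] += 1
            continue
        # 2. element whitelist
        if any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
            removed["element_filter"] += 1
            continue
        # 3. connectivity: keep the largest fragment only
        mol = _largest_fragment(mol)
        # 4. standardizer: neutralize protonation-state charges where valence
        #    permits; quaternary nitrogens and internally compensated groups
        #    (e.g. nitro) stay charged
        mol = _UNCHARGER.uncharge(mol)
        # 5. aromatizer: aromatic perception form
        Chem.SanitizeMol(mol)
        Chem.SetAromaticity(mol)
        # 6. canonical SMILES
        smi = Chem.MolToSmiles(mol)
        # 7. duplicate filter: first occurrence wins
        if smi in seen:
            removed["duplicate_filter"] += 1
            continue
        seen.add(smi)
        out.append(replace(rec, smiles=smi))

    report = CleaningReport(
        n_input=len(records),
        removed_per_step=removed,
        parse_failures=parse_failures,
        n_output=len(out),
    )
    return out, report


def _require_cleaned(records: Sequence[CompoundRecord], name: str) -> None:
    smiles = [r.smiles for r in records]
    canon = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"{name} contains unparseable SMILES {s!r}; run clean_compounds first")
        canon.append(Chem.MolToSmiles(mol))
    if canon != smiles or len(set(canon)) != len(canon):
        raise ValueError(f"{name} is not cleaned (non-canonical or duplicate SMILES); run clean_compounds first")


def assemble_task_dataset(
    positives: Sequence[CompoundRecord],
    negatives: Sequence[CompoundRecord],
) -> list[CompoundRecord]:
    """Union of both classes with labels; overlaps are dropped from negatives only."""
    _require_cleaned(positives, "positives")
    _require_cleaned(negatives, "negatives")
    pos_smiles = {r.smiles for r in positives}
    out = [replace(r, label=1) for r in positives]
    out.extend(replace(r, label=0) for r in negatives if r.smiles not in pos_smiles)
    return out


def imbalance_ratio(dataset: Sequence[CompoundRecord]) -> float:
    """Majority-class count over minority-class count (>= 1)."""
    n_pos = sum(1 for r in dataset if r.label == 1)
    n_neg = sum(1 for r in dataset if r.label == 0)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate single-class dataset")
    return max(n_pos, n_neg) / min(n_pos, n_neg)


def split_dataset(dataset: Sequence[CompoundRecord] | int, seed: int) -> DatasetSplit:
    """9:1 test split, then five independent 4:1 train/validation folds.

    Accepts either the record list or its length. One seed drives the test
    draw and all five fold draws via derived sub-seeds.
    """
    n = dataset if isinstance(dataset, int) else len(dataset)
    if n < 10:
        raise ValueError(f"dataset too small to split: {n} < 10")
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=6)

    perm = np.random.default_rng(sub_seeds[0]).permutation(n)
    n_test = int(round(n / 10))
    test = np.sort(perm[:n_test])
    rest = np.sort(perm[n_test:])

    n_val = int(round(len(rest) / 5))
    folds = []
    for k in range(5):
        fperm = np.random.default_rng(sub_seeds[1 + k]).permutation(len(rest))
        val = np.sort(rest[fperm[:n_val]])
        train = np.sort(rest[fperm[n_val:]])
        folds.append((tuple(int(i) for i in train), tuple(int(i) for i in val)))

    return DatasetSplit(
        test_indices=tuple(int(i) for i in test),
        folds=tuple(folds),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# I/O


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table: CSV (smiles[,label][,id]) or .smi (SMILES [id])."""
    path = Path(path)
    if path.suffix.lower() == ".smi":
        records = []
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            records.append(CompoundRecord(smiles=parts[0], id=parts[1] if len(parts) > 1 else str(i)))
        return records
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: CSV must have a 'smiles' column")
    records = []
    for i, row in df.iterrows():
        label = None
        if "label" in df.columns and not pd.isna(row["label"]):
            label = int(row["label"])
        rid = str(row["id"]) if "id" in df.columns else str(i)
        records.append(CompoundRecord(smiles=row["smiles"], label=label, id=rid))
    return records


def write_compounds(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records as CSV with id, smiles and (where present) label columns."""
    rows = [
        {"id": r.id if r.id is not None else str(i), "smiles": r.smiles, "label": r.label}
        for i, r in enumerate(records)
    ]
    df = pd.DataFrame(rows, columns=["id", "smiles", "label"])
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    df.to_csv(path, index=False)


def split_to_json(split: DatasetSplit) -> str:
    return json.dumps(
        {
            "seed": split.seed,
            "test_indices": list(split.test_indices),
            "folds": [
                {"train": list(tr), "val": list(va)} for tr, va in split.folds
            ],
        }
    )


def split_from_json(text: str) -> DatasetSplit:
    d = json.loads(text)
    return DatasetSplit(
        test_indices=tuple(d["test_indices"]),
        folds=tuple((tuple(f["train"]), tuple(f["val"])) for f in d["folds"]),
        seed=d["seed"],
    )
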