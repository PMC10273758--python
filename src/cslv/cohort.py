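"""Case/control cohort construction and repeated train/test splitting.

Two rule sets are implemented. The biobank-style rules ("ukb"): cases are
women flagged with breast cancer by *both* self report and a cancer
registry; controls are women with no cancer flag of any kind; everyone
else — men, women with only one flag, women with another cancer — is
dropped. The tumor-atlas-style rules ("tcga"): cases are women with breast
cancer, controls are women with any *other* cancer diagnosis (every
participant in such an atlas has some cancer); men are dropped.

Age is never part of the feature schema: germline copy-number state does
not change with age, and the label rules are the only phenotype use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "LabeledDataset",
    "SplitPlan",
    "build_ukb_cohort",
    "build_tcga_cohort",
    "make_splits",
]

logger = logging.getLogger(__name__)

_FORBIDDEN_FEATURES = {"age", "age_at_recruitment", "birth_year"}


@dataclass
class LabeledDataset:
    """Feature table joined with binary labels (1 = breast cancer)."""

    features: pd.DataFrame
    labels: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("labels must be indexed identically to features")
        values = set(pd.unique(self.labels))
        if not values <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(values)}")
        forbidden = _FORBIDDEN_FEATURES & {str(c).lower() for c in self.features.columns}
        if forbidden:
            raise ValueError(f"age-like columns are not allowed in features: {sorted(forbidden)}")

    @property
    def n_cases(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/test split plan.

    ``repeats`` independent splits (the source analysis used at least 10),
    each holding out ``test_fraction`` of the samples; ``fold_count`` is
    the cross-validation granularity passed to fold-based learners.
    Per-repeat seeds derive deterministically from ``seed``.
    """

    repeats: int = 10
    test_fraction: float = 0.15
    fold_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.fold_count < 2:
            raise ValueError("fold_count must be >= 2")

    def repeat_seeds(self) -> list[int]:
        states = np.random.SeedSequence(self.seed).generate_state(self.repeats, dtype=np.uint32)
        return [int(s) % (2**31) for s in states]


def _apply_rules(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    case_mask: pd.Series,
    control_mask: pd.Series,
    provenance: str,
) -> LabeledDataset:
    pheno = phenotypes.set_index("sample_id")
    missing = features.index.difference(pheno.index)
    if len(missing):
        raise ValueError(f"phenotypes missing for {len(missing)} feature sample(s): "
                         f"{list(missing[:5])}...")
    case_ids = pheno.index[case_mask.to_numpy()].intersection(features.index)
    control_ids = pheno.index[control_mask.to_numpy()].intersection(features.index)
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError(
            f"{provenance}: rule application yields {len(case_ids)} cases and "
            f"{len(control_ids)} controls"
        )
    keep = features.index[features.index.isin(case_ids.union(control_ids))]
    labels = pd.Series(
        np.where(keep.isin(case_ids), 1, 0), index=keep, name="label", dtype=np.int8
    )
    logger.info(
        "%s cohort: %d cases, %d controls (%d samples dropped by rules)",
        provenance, int(labels.sum()), int((labels == 0).sum()), len(features) - len(keep),
    )
    return LabeledDataset(features.loc[keep], labels, provenance=provenance)


def build_ukb_cohort(features: pd.DataFrame, phenotypes: pd.DataFrame) -> LabeledDataset:
    """Biobank rules: dual-flag breast-cancer women vs cancer-free women."""
    pheno = phenotypes.set_index("sample_id")
    female = pheno["sex"] == "F"
    breast = pheno["cancer_type"] == "breast"
    cases = female & pheno["self_report_cancer"] & pheno["registry_cancer"] & breast
    controls = female & ~pheno["self_report_cancer"] & ~pheno["registry_cancer"]
    return _apply_rules(features, phenotypes, cases, controls, provenance="ukb")


def build_tcga_cohort(features: pd.DataFrame, phenotypes: pd.DataFrame) -> LabeledDataset:
    """Tumor-atlas rules: breast-cancer women vs women with another cancer."""
    pheno = phenotypes.set_index("sample_id")
    female = pheno["sex"] == "F"
    has_cancer = pheno["cancer_type"] != ""
    breast = pheno["cancer_type"] == "breast"
    cases = female & breast
    controls = female & has_cancer & ~breast
    return _apply_rules(features, phenotypes, cases, controls, provenance="tcga")


def make_splits(
    dataset: LabeledDataset, plan: SplitPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified repeated train/test splits as (train_idx, test_idx) pairs.

    Deterministic given ``plan.seed``; each repeat uses its own derived
    seed, so repeats differ while the whole sequence is reproducible.
    """
    y = dataset.labels.to_numpy()
    indices = np.arange(len(y))
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for repeat_seed in plan.repeat_seeds():
        train_idx, test_idx = train_test_split(
            indices,
            test_size=plan.test_fraction,
            stratify=y,
            random_state=repeat_seed,
            shuffle=True,
        )
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError("split produced a single-class partition; dataset too small")
        splits.append((np.sort(train_idx), np.sort(test_idx)))
    return splits
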