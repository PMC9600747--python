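"""Stimulus-specific gene-module eigengenes on cell-type median profiles.

A module eigengene is the first principal component of the module's
standardized expression over the profile axis (here: cell-type medians), a
one-number-per-profile summary of a stimulus-response program.  Eigengenes
are then Pearson-correlated with one-hot cell-type indicators to read off
which cell type carries which polarization imprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import hierarchical_order, standardize_genes

logger = logging.getLogger(__name__)

#: modules with less than this member coverage in the matrix are flagged
COVERAGE_FLAG = 0.5


@dataclass
class ModuleDefinition:
    module_id: str
    genes: list[str]
    stimuli: list[str] = field(default_factory=list)


@dataclass
class EigengeneResult:
    module_id: str
    eigengene: pd.Series  # one value per profile, unit norm
    variance_explained: float
    coverage: float
    flagged: bool


def module_eigengene(profiles: pd.DataFrame, module: ModuleDefinition,
                     min_members: int = 2) -> EigengeneResult:
    """First principal component of a module over cell-type median profiles.

    Rows (genes) are standardized across profiles; the eigengene is the
    first right singular vector of the standardized member submatrix, sign-
    fixed so that its correlation with the module's mean standardized
    expression is nonnegative.
    """
    if profiles.shape[1] < 3 and min_members >= 2:
        raise ValueError("need at least 3 profiles for an eigengene")
    present = [g for g in module.genes if g in profiles.index]
    if len(present) < min_members:
        raise ValueError(
            f"module {module.module_id!r}: only {len(present)} member gene(s) "
            f"present, need >= {min_members}"
        )
    coverage = len(present) / len(module.genes)
    flagged = coverage < COVERAGE_FLAG
    if flagged:
        logger.warning("module %s: coverage %.2f below %.2f",
                       module.module_id, coverage, COVERAGE_FLAG)

    z = standardize_genes(profiles.loc[present])
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    eigengene = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())

    mean_profile = z.mean(axis=0).to_numpy()
    if np.dot(eigengene, mean_profile - mean_profile.mean()) < 0:
        eigengene = -eigengene
    return EigengeneResult(
        module_id=module.module_id,
        eigengene=pd.Series(eigengene, index=profiles.columns,
                            name=module.module_id),
        variance_explained=var_explained,
        coverage=coverage,
        flagged=flagged,
    )


def correlate_modules_celltypes(eigengenes: list[EigengeneResult],
                                cell_types: list[str] | None = None,
                                cluster: bool = False) -> pd.DataFrame:
    """Pearson correlation of each eigengene with one-hot cell-type indicators.

    The profile axis of the eigengenes is the cell types themselves (median
    profiles), so the indicator for cell type ``c`` is 1 at profile ``c``
    and 0 elsewhere.  With ``cluster=True`` rows and columns are reordered
    by complete-linkage Euclidean clustering.
    """
    if not eigengenes:
        raise ValueError("no eigengenes given")
    profile_axis = eigengenes[0].eigengene.index
    for e in eigengenes[1:]:
        if not e.eigengene.index.equals(profile_axis):
            raise ValueError("eigengenes do not share the profile axis")
    if cell_types is None:
        cell_types = list(profile_axis)

    rows = {}
    for e in eigengenes:
        v = e.eigengene.to_numpy()
        if np.std(v) == 0:
            raise ValueError(
                f"eigengene {e.module_id!r} is constant; correlation undefined"
            )
        rows[e.module_id] = {
            ct: float(np.corrcoef(v, (profile_axis == ct).astype(float))[0, 1])
            for ct in cell_types
        }
    corr = pd.DataFrame(rows).T.loc[[e.module_id for e in eigengenes], cell_types]
    corr.index.name = "module_id"
    if cluster and corr.shape[0] > 1:
        corr = corr.loc[hierarchical_order(corr, axis=0)]
    if cluster and corr.shape[1] > 1:
        corr = corr[hierarchical_order(corr, axis=1)]
    return corr


def modules_from_gmt(sets: dict[str, tuple[str, list[str]]]) -> list[ModuleDefinition]:
    """Build module definitions from GMT entries, stimuli in the description."""
    return [
        ModuleDefinition(module_id=name, genes=members,
                         stimuli=[s for s in desc.split(",") if s and s != "na"])
        for name, (desc, members) in sets.items()
    ]
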