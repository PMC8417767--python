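"""Free-energy model comparison and random-effects family inference.

Model evidences are compared per subject via ΔF = F_i − F_j (approximate log
Bayes factors); |ΔF| > 3 marks one model as roughly twenty times more likely
than the other (exp(3) ≈ 20).  Families of models are compared across
subjects with random-effects Bayesian model selection: member evidences are
combined by log-sum-exp under a uniform within-family prior, family
frequencies get a Dirichlet prior, and a Gibbs sampler yields each family's
exceedance probability — the posterior belief that it is the most frequent
family in the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp


class ComparisonError(ValueError):
    pass


@dataclass
class ModelEvidenceTable:
    """Subjects × models free energies with family labels.

    ``model_labels`` are (orientation method, location surface, orientation
    surface) triples; ``families`` maps a family label to member model
    indices and must partition the model set.
    """

    F: np.ndarray
    model_labels: list[tuple[str, str, str]]
    families: dict[str, list[int]] | None = None

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=np.float64))
        if self.F.shape[1] != len(self.model_labels):
            raise ComparisonError("label count does not match model count")
        if self.families is not None:
            _check_partition(self.families, self.F.shape[1])

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]

    @property
    def n_models(self) -> int:
        return self.F.shape[1]


def _check_partition(families: dict[str, list[int]], n_models: int) -> None:
    seen: list[int] = []
    for name, idx in families.items():
        if len(idx) == 0:
            raise ComparisonError(f"family {name!r} is empty")
        seen.extend(idx)
    if sorted(seen) != list(range(n_models)):
        raise ComparisonError("families must partition the model set")


GROUPINGS = {
    "method": lambda lab: lab[0],
    "location": lambda lab: lab[1],
    "orientation": lambda lab: lab[2],
    "method-location": lambda lab: f"{lab[0]}/{lab[1]}",
}


def families_from_grouping(table: ModelEvidenceTable,
                           grouping: str) -> dict[str, list[int]]:
    """Group models into families by label component(s)."""
    if grouping not in GROUPINGS:
        raise ComparisonError(
            f"unknown grouping {grouping!r}; choose from {sorted(GROUPINGS)}")
    key = GROUPINGS[grouping]
    fams: dict[str, list[int]] = {}
    for i, lab in enumerate(table.model_labels):
        fams.setdefault(key(lab), []).append(i)
    return fams


def delta_f(table: ModelEvidenceTable,
            reference_model: int | tuple) -> np.ndarray:
    """Subjects × models free-energy differences versus a reference model."""
    if isinstance(reference_model, (tuple, list)):
        try:
            ref = table.model_labels.index(tuple(reference_model))
        except ValueError:
            raise ComparisonError(f"unknown reference {reference_model!r}")
    else:
        ref = int(reference_model)
        if not 0 <= ref < table.n_models:
            raise ComparisonError(f"reference index {ref} out of range")
    return table.F - table.F[:, [ref]]


def significant(delta_f_value: float,
                threshold: float = 3.0) -> tuple[str, float]:
    """Classify a ΔF value and report the implied Bayes factor exp(|ΔF|).

    Strictly greater than +threshold → "better", strictly below −threshold →
    "worse", otherwise "indistinguishable" (so ΔF = ±3 is itself
    indistinguishable); exp(3) ≈ 20.09, i.e. one model about twenty times
    more likely than the other at the threshold.
    """
    x = float(delta_f_value)
    if not np.isfinite(x):
        raise ComparisonError("free-energy difference must be finite")
    verdict = ("better" if x > threshold
               else "worse" if x < -threshold else "indistinguishable")
    with np.errstate(over="ignore"):
        bayes_factor = float(np.exp(abs(x)))  # inf for very large |dF|
    return verdict, bayes_factor


def family_log_evidence(table: ModelEvidenceTable,
                        families: dict[str, list[int]]) -> np.ndarray:
    """Per-subject family log evidence under a uniform within-family prior.

    logsumexp of member free energies minus log member count; subjects ×
    families, column order = insertion order of ``families``.
    """
    _check_partition(families, table.n_models)
    cols = []
    for idx in families.values():
        cols.append(logsumexp(table.F[:, idx], axis=1) - np.log(len(idx)))
    return np.column_stack(cols)


def compare_families(table: ModelEvidenceTable,
                     grouping: str | dict[str, list[int]],
                     n_samples: int = 100_000,
                     rng: np.random.Generator | int | None = None,
                     alpha0: float = 1.0,
                     burn_in: int = 1000) -> dict[str, float]:
    """Random-effects exceedance probability per family.

    Hierarchical Dirichlet-multinomial model over family frequencies r:
    r ~ Dir(α₀·1); each subject uses one family drawn from r; evidences enter
    through the per-subject family log evidence.  Gibbs sampling alternates
    subject assignments and r; EP_k is the fraction of posterior draws in
    which family k has the largest frequency, so the EPs sum to 1 exactly.
    """
    if isinstance(grouping, str):
        families = families_from_grouping(table, grouping)
    else:
        families = grouping
    if len(families) < 2:
        raise ComparisonError("need at least 2 families")
    rng = np.random.default_rng(rng)
    lme = family_log_evidence(table, families)        # (S, K)
    S, K = lme.shape
    lme = lme - lme.max(axis=1, keepdims=True)
    wins = np.zeros(K, dtype=np.int64)
    r = np.full(K, 1.0 / K)
    for it in range(burn_in + n_samples):
        logp = lme + np.log(r)[None, :]
        p = np.exp(logp - logp.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        u = rng.uniform(size=(S, 1))
        z = (p.cumsum(axis=1) < u).sum(axis=1)
        counts = np.bincount(z, minlength=K)
        r = rng.dirichlet(alpha0 + counts)
        if it >= burn_in:
            wins[int(np.argmax(r))] += 1
    ep = wins / wins.sum()
    return {name: float(e) for name, e in zip(families, ep)}


def exact_two_family_ep(table: ModelEvidenceTable,
                        families: dict[str, list[int]],
                        alpha0: float = 1.0) -> dict[str, float]:
    """Exact exceedance probabilities for two families by enumeration.

    Marginalizes subject assignments exactly (2^S terms) and integrates the
    Dirichlet posterior analytically via the Beta CDF; serves as a
    deterministic oracle for the Gibbs sampler on small tables.
    """
    from itertools import product

    from scipy.special import betaln
    from scipy.stats import beta as beta_dist

    if len(families) != 2:
        raise ComparisonError("exact enumeration supports exactly 2 families")
    lme = family_log_evidence(table, families)
    S = lme.shape[0]
    log_ws, eps1 = [], []
    for z in product(range(2), repeat=S):
        z = np.array(z)
        counts = np.bincount(z, minlength=2)
        log_w = lme[np.arange(S), z].sum() \
            + betaln(alpha0 + counts[0], alpha0 + counts[1]) \
            - betaln(alpha0, alpha0)
        log_ws.append(log_w)
        eps1.append(beta_dist.sf(0.5, alpha0 + counts[0], alpha0 + counts[1]))
    log_ws = np.array(log_ws)
    w = np.exp(log_ws - logsumexp(log_ws))
    ep1 = float(w @ np.array(eps1))
    names = list(families)
    return {names[0]: ep1, names[1]: 1.0 - ep1}


# ---------------------------------------------------------------------------
# I/O

def write_evidence_table(table: ModelEvidenceTable, path: str | Path) -> None:
    rows = []
    for s in range(table.n_subjects):
        for m, lab in enumerate(table.model_labels):
            rows.append({"subject": s, "method": lab[0],
                         "location_surface": lab[1],
                         "orientation_surface": lab[2],
                         "F": table.F[s, m]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_evidence_table(path: str | Path) -> ModelEvidenceTable:
    df = pd.read_csv(path, sep="\t")
    labels = list(dict.fromkeys(
        zip(df["method"], df["location_surface"], df["orientation_surface"])))
    subjects = sorted(df["subject"].unique())
    F = np.full((len(subjects), len(labels)), np.nan)
    for _, row in df.iterrows():
        s = subjects.index(row["subject"])
        m = labels.index((row["method"], row["location_surface"],
                          row["orientation_surface"]))
        F[s, m] = row["F"]
    if np.any(np.isnan(F)):
        raise ComparisonError("incomplete subjects × models table")
    return ModelEvidenceTable(F, [tuple(l) for l in labels])
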