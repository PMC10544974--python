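"""Field-trial design generation.

Two designs common in cereal breeding are supported:

* **alpha-lattice** — a resolvable incomplete-block design: every entry appears
  once per complete replicate, and each replicate is partitioned into
  incomplete blocks of equal size.
* **augmented with repeating checks** — test entries are unreplicated; a small
  set of check cultivars is repeated across incomplete blocks so that the
  design retains an estimate of plot error.

Designs can span several environments (year-location combinations); the layout
is re-randomized independently within each environment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

AUGMENTED = "augmented_with_checks"
ALPHA_LATTICE = "alpha_lattice"


@dataclass
class TrialDesign:
    """Plot-to-genotype/environment/replicate/block mapping.

    Attributes
    ----------
    plots : pandas.DataFrame
        One row per plot with columns ``plot_id``, ``genotype``,
        ``environment``, ``replicate``, ``block``, ``is_check``.
    design_kind : str
        ``"alpha_lattice"`` or ``"augmented_with_checks"``.
    n_entries : int
        Number of unique genotypes (checks included for augmented designs).
    n_checks : int
        Number of replicated check genotypes (0 for alpha-lattice).
    x : int
        Number of environments.
    r : int
        Number of complete replications per environment (1 for augmented
        designs, where only checks are replicated).
    """

    plots: pd.DataFrame
    design_kind: str
    n_entries: int
    n_checks: int
    x: int
    r: int
    extra: dict = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.plots["genotype"].unique())

    def __post_init__(self) -> None:
        counts = self.plots.groupby("plot_id").size()
        if (counts > 1).any():
            raise DesignError("duplicate plot_id in design")


def _entry_labels(n_entries: int, n_checks: int) -> tuple[list[str], list[str]]:
    checks = [f"check_{i + 1:02d}" for i in range(n_checks)]
    tests = [f"entry_{i + 1:04d}" for i in range(n_entries - n_checks)]
    return checks, tests


def generate_trial_design(
    design_kind: str,
    n_entries: int,
    *,
    n_checks: int = 0,
    r: int = 1,
    block_size: int | None = None,
    x: int = 1,
    check_reps: int = 3,
    seed: int | None = None,
) -> TrialDesign:
    """Generate a randomized trial design.

    Parameters
    ----------
    design_kind : str
        ``"alpha_lattice"`` or ``"augmented_with_checks"``.
    n_entries : int
        Unique genotypes. For augmented designs this count includes the
        ``n_checks`` check cultivars.
    n_checks : int
        Replicated checks (augmented designs only).
    r : int
        Complete replications (alpha-lattice; must be >= 2).
    block_size : int, optional
        Incomplete-block size for the alpha-lattice. Must divide
        ``n_entries``. Defaults to the largest divisor of ``n_entries`` not
        exceeding ``sqrt(n_entries)`` (falls back to one block per replicate).
    x : int
        Number of environments; the design is laid out afresh in each.
    check_reps : int
        Total occurrences of each check per environment in an augmented
        design (first occurrence included), which equals the number of
        incomplete blocks.
    seed : int, optional
        Seed for the randomization; fixed seed gives a bit-reproducible
        design.

    Returns
    -------
    TrialDesign

    Notes
    -----
    Plot counts per environment follow the standard arithmetic:
    ``n_entries * r`` for an alpha-lattice and
    ``n_entries + n_checks * (check_reps - 1)`` for an augmented design.
    """
    if n_entries < 1:
        raise DesignError("n_entries must be >= 1")
    if x < 1:
        raise DesignError("x (environments) must be >= 1")
    rng = np.random.default_rng(seed)

    if design_kind == ALPHA_LATTICE:
        plots = _alpha_lattice(n_entries, r, block_size, x, rng)
        n_checks_out, r_out = 0, r
    elif design_kind == AUGMENTED:
        plots = _augmented(n_entries, n_checks, check_reps, x, rng)
        n_checks_out, r_out = n_checks, 1
    else:
        raise DesignError(f"unknown design_kind: {design_kind!r}")

    return TrialDesign(
        plots=plots,
        design_kind=design_kind,
        n_entries=n_entries,
        n_checks=n_checks_out,
        x=x,
        r=r_out,
    )


def _default_block_size(n_entries: int) -> int:
    limit = int(np.sqrt(n_entries))
    for s in range(limit, 1, -1):
        if n_entries % s == 0:
            return s
    return n_entries  # prime entry count: one block per replicate


def _alpha_lattice(n_entries, r, block_size, x, rng) -> pd.DataFrame:
    if r < 2:
        raise DesignError("alpha-lattice requires r >= 2 complete replicates")
    if block_size is None:
        block_size = _default_block_size(n_entries)
    if block_size < 1 or n_entries % block_size != 0:
        raise DesignError(
            f"block_size {block_size} does not divide n_entries {n_entries}"
        )
    _, tests = _entry_labels(n_entries, 0)
    genotypes = np.array(tests)
    rows = []
    for e in range(1, x + 1):
        env = f"env_{e}"
        plot_no = 0
        for rep in range(1, r + 1):
            order = rng.permutation(n_entries)
            for i, gi in enumerate(order):
                plot_no += 1
                rows.append(
                    (
                        f"{env}_p{plot_no:04d}",
                        genotypes[gi],
                        env,
                        f"rep_{rep}",
                        f"rep_{rep}_b{i // block_size + 1:02d}",
                        False,
                    )
                )
    return _frame(rows)


def _augmented(n_entries, n_checks, check_reps, x, rng) -> pd.DataFrame:
    if n_checks < 0 or n_checks > n_entries:
        raise DesignError("n_checks must be between 0 and n_entries")
    if n_checks > 0 and check_reps < 2:
        raise DesignError("check_reps must be >= 2 so checks are replicated")
    checks, tests = _entry_labels(n_entries, n_checks)
    n_blocks = check_reps if n_checks > 0 else 1
    rows = []
    for e in range(1, x + 1):
        env = f"env_{e}"
        test_order = rng.permutation(len(tests))
        block_of_test = np.array_split(test_order, n_blocks)
        plot_no = 0
        for b in range(n_blocks):
            names = [tests[i] for i in block_of_test[b]] + checks
            names = [names[i] for i in rng.permutation(len(names))]
            for g in names:
                plot_no += 1
                rows.append(
                    (
                        f"{env}_p{plot_no:04d}",
                        g,
                        env,
                        "rep_1",
                        f"b{b + 1:02d}",
                        g in checks,
                    )
                )
    return _frame(rows)


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["plot_id", "genotype", "environment", "replicate", "block", "is_check"],
    )
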