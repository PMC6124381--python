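"""Synthetic compositional data with known balance structure.

The generator draws ilr coordinates from independent normals on the
balances of a known SBP and maps them back to the simplex through the
orthonormal contrast matrix (a logistic-normal model). Because this is the
exact inverse of the analysis pipeline, recomputing balances from the
simulated table recovers the generating means and standard deviations —
a sharp end-to-end test. Optionally each sample is resampled as multinomial
counts at a fixed sequencing depth, which introduces the structural-looking
zeros typical of meta-genomics count tables, and a location shift can be
injected on one balance for a fraction of the samples to emulate a
case/control difference.

The module also packages two small printed fixtures: a 20 x 5 household
expenditures table and its hand-built 5 x 4 SBP, the classic worked example
for balance analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CompositionTable, DomainError, StructuralError,
                   closure, validate_composition)
from .sbp import MergeTree, SbpMatrix, sbp_to_contrast, tree_to_sbp, validate_sbp
from skbio import TreeNode

__all__ = [
    "SyntheticSpec",
    "SimulationResult",
    "simulate_compositions",
    "random_merge_tree",
    "load_fixture",
]


# ---------------------------------------------------------------------------
# Packaged fixtures (household expenditures, 20 samples x 5 components,
# and the matching 4-balance SBP)
# ---------------------------------------------------------------------------

_EXPENDITURES_TSV = """\
sample\thousing\tfoodstuffs\talcohol\tother\tservices
i01\t640\t328\t147\t169\t196
i02\t1800\t484\t515\t2291\t912
i03\t2085\t445\t725\t8373\t1732
i04\t616\t331\t126\t117\t149
i05\t875\t368\t191\t290\t275
i06\t770\t364\t196\t242\t236
i07\t990\t415\t284\t588\t420
i08\t414\t305\t94\t68\t112
i09\t1394\t440\t393\t1161\t636
i10\t1285\t374\t363\t785\t487
i11\t1102\t469\t243\t496\t388
i12\t1717\t452\t452\t1977\t832
i13\t1549\t454\t424\t1345\t676
i14\t838\t386\t155\t208\t222
i15\t845\t386\t211\t317\t280
i16\t1130\t394\t271\t490\t386
i17\t1765\t466\t524\t2133\t822
i18\t1195\t443\t329\t974\t523
i19\t2180\t521\t553\t2781\t1010
i20\t1017\t410\t225\t419\t345
"""

_EXPENDITURES_SBP_TSV = """\
component\tz1\tz2\tz3\tz4
housing\t1\t1\t0\t0
foodstuffs\t1\t-1\t1\t0
alcohol\t1\t-1\t-1\t0
other\t-1\t0\t0\t1
services\t-1\t0\t0\t-1
"""


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``expenditures`` returns the 20 x 5 CompositionTable;
    ``expenditures_sbp`` its 5 x 4 SbpMatrix.
    """
    if name == "expenditures":
        df = pd.read_csv(io.StringIO(_EXPENDITURES_TSV), sep="\t", index_col=0)
        return validate_composition(df)
    if name == "expenditures_sbp":
        df = pd.read_csv(io.StringIO(_EXPENDITURES_SBP_TSV), sep="\t",
                         index_col=0)
        return validate_sbp(df)
    raise KeyError(f"unknown fixture {name!r}; "
                   "available: expenditures, expenditures_sbp")


# ---------------------------------------------------------------------------
# Random trees / SBPs
# ---------------------------------------------------------------------------

def random_merge_tree(component_ids, rng) -> MergeTree:
    """Uniform-ish random strictly binary merge tree over the given labels.

    Built by repeated random pairwise merges (like a random agglomeration
    order); reproducible from the supplied Generator.
    """
    rng = np.random.default_rng(rng)
    nodes = [TreeNode(name=c) for c in component_ids]
    if len(nodes) < 2:
        raise StructuralError("need at least 2 components for a merge tree")
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(TreeNode(children=[left, right]))
    return MergeTree(nodes[0])


# ---------------------------------------------------------------------------
# Logistic-normal simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated data set.

    group_shift, if given, is ``(balance_id, delta, fraction)``: the last
    ``fraction`` of samples (group "B") receive an additive shift ``delta``
    on that balance's ilr coordinate before back-transformation.
    """

    D: int
    n: int
    basis_sbp: SbpMatrix | str = "random-tree"
    balance_means: np.ndarray | None = None
    balance_sds: np.ndarray | None = None
    sequencing_depth: int | None = None
    group_shift: tuple | None = None
    seed: int = 0


@dataclass(frozen=True)
class SimulationResult:
    table: CompositionTable
    sbp: SbpMatrix
    balance_means: pd.Series
    balance_sds: pd.Series
    sample_groups: pd.Series = field(default=None)


def simulate_compositions(spec: SyntheticSpec) -> SimulationResult:
    """Draw logistic-normal compositions on the balances of a known SBP.

    ilr coordinates are sampled per balance from N(mean, sd^2), shifted for
    the designated group if requested, and inverted through the contrast
    matrix: x = closure(exp(coords @ Psi)). With ``sequencing_depth`` set,
    each row is additionally resampled as multinomial counts at that depth,
    producing integer tables with zeros at rare parts. Fully reproducible
    from ``spec.seed``.
    """
    if spec.D < 2 or spec.n < 1:
        raise StructuralError(f"need D>=2 and n>=1, got D={spec.D}, n={spec.n}")
    rng = np.random.default_rng(spec.seed)

    if isinstance(spec.basis_sbp, SbpMatrix):
        sbp = spec.basis_sbp
        if sbp.n_components != spec.D:
            raise StructuralError(
                f"basis SBP has {sbp.n_components} components, spec.D={spec.D}"
            )
    elif spec.basis_sbp == "random-tree":
        labels = [f"taxon_{i + 1}" for i in range(spec.D)]
        sbp = tree_to_sbp(random_merge_tree(labels, rng))
    else:
        raise StructuralError(
            "basis_sbp must be an SbpMatrix or the string 'random-tree'"
        )

    m = spec.D - 1
    means = (np.zeros(m) if spec.balance_means is None
             else np.asarray(spec.balance_means, dtype=float))
    sds = (np.ones(m) if spec.balance_sds is None
           else np.asarray(spec.balance_sds, dtype=float))
    if means.shape != (m,) or sds.shape != (m,):
        raise StructuralError(
            f"balance_means and balance_sds must have length D-1 = {m}"
        )
    if np.any(sds < 0):
        raise DomainError("balance_sds must be non-negative")

    coords = means + sds * rng.standard_normal((spec.n, m))
    groups = pd.Series("A", index=[f"sample_{i + 1}" for i in range(spec.n)])
    if spec.group_shift is not None:
        balance_id, delta, fraction = spec.group_shift
        if balance_id not in sbp.balance_ids:
            raise StructuralError(f"group_shift balance {balance_id!r} "
                                  "not in the SBP")
        if not 0 < fraction < 1:
            raise DomainError("group_shift fraction must be in (0, 1)")
        n_b = int(round(spec.n * fraction))
        if not 0 < n_b < spec.n:
            raise DomainError("group_shift fraction leaves an empty group")
        j = sbp.balance_ids.index(balance_id)
        coords[-n_b:, j] += delta
        groups.iloc[-n_b:] = "B"

    psi = sbp_to_contrast(sbp).values  # (D-1) x D
    parts = np.exp(coords @ psi)
    table = pd.DataFrame(parts, index=groups.index,
                         columns=sbp.component_ids)
    comp = closure(CompositionTable(table))

    if spec.sequencing_depth is not None:
        depth = int(spec.sequencing_depth)
        if depth <= 0:
            raise DomainError("sequencing_depth must be a positive integer")
        counts = np.vstack([rng.multinomial(depth, p)
                            for p in comp.values])
        comp = validate_composition(
            pd.DataFrame(counts, index=groups.index,
                         columns=sbp.component_ids),
            allow_zero=True,
        )

    idx = pd.Index(sbp.balance_ids)
    return SimulationResult(
        table=comp,
        sbp=sbp,
        balance_means=pd.Series(means, index=idx, name="mean"),
        balance_sds=pd.Series(sds, index=idx, name="sd"),
        sample_groups=groups,
    )
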