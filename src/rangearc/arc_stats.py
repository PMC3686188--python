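"""Sympatry/symmetry indexes and the age-range-correlation fits.

The node-based sympatry index compares the joint (union) ranges of the two
clades meeting at a node: overlap area divided by the smaller clade range
area, bounded by [0, 1].  The symmetry index is the smaller clade range
divided by the summed clade ranges, bounded by (0, 0.5].  The species-level
variant takes the mean and maximum of pairwise overlap proportions across
all cross-clade tip pairs at a node.  Indexes are arcsine transformed (the
symmetry index doubled first) and regressed on node age, linearly and with
a three-parameter logistic sigmoid y = a / (1 + b e^(-c Age)).

Interpretive rules: a positive sympatry-age slope with intercept near 0 is
the allopatric signature (young nodes allopatric, secondary contact with
time); a negative slope suggests sympatric divergence; a positive
symmetry-age slope suggests peripatric divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from rangearc.phylo_io import DatedTree, NodeRecord, node_table, validate_tree
from rangearc.range_geometry import RangeGeom, overlap_area, union_range

__all__ = [
    "ArcFit",
    "sympatry_index",
    "symmetry_index",
    "species_pair_sympatry",
    "arcsine_transform",
    "fit_linear",
    "fit_logistic3",
    "compare_models",
    "build_arc_table",
    "logistic3",
]


def sympatry_index(clade_a: RangeGeom, clade_b: RangeGeom) -> float:
    """Range overlap divided by the smaller of the two clade ranges.

    0 = fully allopatric; 1 = the smaller range nested in (or coincident
    with) the larger.  Symmetric in its arguments.
    """
    _require_positive_areas(clade_a, clade_b)
    return overlap_area(clade_a, clade_b) / min(clade_a.area, clade_b.area)


def symmetry_index(clade_a: RangeGeom, clade_b: RangeGeom) -> float:
    """Smaller clade range divided by the sum of both clade ranges.

    Bounded by 0.5 (reached iff the two ranges have equal area);
    persistently low values at young nodes indicate peripatric splits.
    """
    _require_positive_areas(clade_a, clade_b)
    return min(clade_a.area, clade_b.area) / (clade_a.area + clade_b.area)


def _require_positive_areas(a: RangeGeom, b: RangeGeom) -> None:
    for r in (a, b):
        if r.area <= 0:
            raise ValueError(f"zero-area range for {r.taxon_id!r}")


def species_pair_sympatry(
    node: NodeRecord, ranges: dict[str, RangeGeom]
) -> tuple[float, float]:
    """Mean and maximum pairwise overlap proportion across the node.

    Every cross-clade tip pair (x in one daughter clade, y in the other)
    contributes overlap / min(area_x, area_y); within-clade pairs are
    excluded because they do not date from this node's divergence.
    """
    for tip in node.tips:
        if tip not in ranges:
            raise KeyError(f"no range for tip {tip!r}")
    vals = [
        sympatry_index(ranges[x], ranges[y])
        for x in sorted(node.tips_left)
        for y in sorted(node.tips_right)
    ]
    return float(np.mean(vals)), float(max(vals))


def arcsine_transform(p: float, kind: str = "index", variant: str = "sqrt") -> float:
    """Variance-stabilizing arcsine transform of a proportion, in radians.

    ``kind="index"`` expects p in [0, 1]; ``kind="symmetry"`` expects
    p in (0, 0.5] and doubles it first so the transform again spans
    [0, pi/2].  ``variant="sqrt"`` applies arcsin(sqrt(.)) (the standard
    choice for proportions); ``variant="plain"`` applies arcsin(.) directly.
    """
    if kind == "symmetry":
        if not 0.0 < p <= 0.5 + 1e-12:
            raise ValueError(f"symmetry index {p} outside (0, 0.5]")
        p = min(2.0 * p, 1.0)
    elif kind == "index":
        if not -1e-12 <= p <= 1.0 + 1e-12:
            raise ValueError(f"proportion {p} outside [0, 1]")
        p = min(max(p, 0.0), 1.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if variant == "sqrt":
        return math.asin(math.sqrt(p))
    if variant == "plain":
        return math.asin(p)
    raise ValueError(f"unknown arcsine variant {variant!r}")


@dataclass
class ArcFit:
    """A fitted sympatry-vs-age model (linear or three-parameter logistic)."""

    model: str  # "linear" | "logistic3"
    response: str
    params: dict[str, float]
    r2: float
    df: int
    n_points: int
    p_slope: float | None = None
    p_intercept: float | None = None
    converged: bool = True
    message: str = ""
    ss_res: float = field(default=float("nan"), repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.model == "linear":
            return self.params["intercept"] + self.params["slope"] * ages
        return logistic3(ages, self.params["a"], self.params["b"], self.params["c"])

    def aic(self) -> float:
        """Gaussian-residual AIC: n ln(SSres/n) + 2k (k = params + error var)."""
        n = self.n_points
        ss = max(self.ss_res, 1e-300)
        return n * math.log(ss / n) + 2 * (self.n_params + 1)


def fit_linear(ages, y, response: str = "node_sympatry") -> ArcFit:
    """Ordinary least squares of (transformed) index on node age.

    Reports slope/intercept estimates with two-sided t-test p-values, r²,
    and residual df.  Degenerate but legal inputs (constant y) return
    slope 0 with r² defined as 0.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.shape != y.shape:
        raise ValueError("ages and y must have equal length")
    n = len(ages)
    if n < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; slope not estimable")
    X = sm.add_constant(ages)
    res = sm.OLS(y, X).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float(res.rsquared) if sst > 0 else 0.0
    return ArcFit(
        model="linear",
        response=response,
        params={"intercept": float(res.params[0]), "slope": float(res.params[1])},
        r2=r2,
        df=int(res.df_resid),
        n_points=n,
        p_slope=float(res.pvalues[1]) if sst > 0 else 1.0,
        p_intercept=float(res.pvalues[0]),
        ss_res=float(res.ssr),
    )


def logistic3(age, a: float, b: float, c: float) -> np.ndarray:
    """Three-parameter logistic sigmoid a / (1 + b e^(-c age))."""
    age = np.asarray(age, dtype=float)
    return a / (1.0 + b * np.exp(-c * age))


_N_RESTARTS = 20


def fit_logistic3(
    ages, y, response: str = "node_sympatry", seed: int = 0
) -> ArcFit:
    """Nonlinear least squares for y = a / (1 + b e^(-c Age)), a,b,c > 0.

    Deterministic: the initial guess sets a0 = 1.05 max(y), takes c0 from
    the slope of log((a0-y)/y) on age where defined, and solves b0 from the
    youngest point; up to 20 restarts jitter the guess by factors U(0.5, 2)
    drawn from a generator seeded with ``seed``.  Unidentifiable data (e.g.
    constant y) yields a flagged non-converged fit rather than an exception.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.shape != y.shape:
        raise ValueError("ages and y must have equal length")
    n = len(ages)
    if n < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least two distinct ages")
    sst = float(np.sum((y - y.mean()) ** 2))
    ymax = float(np.max(y))
    if sst == 0 or ymax <= 0:
        return ArcFit(
            model="logistic3",
            response=response,
            params={"a": ymax if ymax > 0 else 1.0, "b": 1.0, "c": 0.0},
            r2=0.0,
            df=n - 3,
            n_points=n,
            converged=False,
            message="response constant or non-positive; sigmoid unidentifiable",
            ss_res=sst,
        )
    theta0 = _logistic3_init(ages, y)
    rng = np.random.default_rng(seed)

    def residuals(log_theta):
        with np.errstate(over="ignore"):
            a, b, c = np.exp(np.clip(log_theta, -500, 500))
            return logistic3(ages, a, b, c) - y

    best = None
    guesses = [theta0] + [
        theta0 * rng.uniform(0.5, 2.0, size=3) for _ in range(_N_RESTARTS)
    ]
    for guess in guesses:
        try:
            sol = least_squares(
                residuals, np.log(guess), method="lm", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        return ArcFit(
            model="logistic3",
            response=response,
            params={"a": float("nan"), "b": float("nan"), "c": float("nan")},
            r2=0.0,
            df=n - 3,
            n_points=n,
            converged=False,
            message="optimizer failed from all starts",
            ss_res=float("nan"),
        )
    a, b, c = np.exp(best.x)
    ss_res = float(2 * best.cost)
    r2 = max(0.0, min(1.0, 1.0 - ss_res / sst))
    # near-zero c means the sigmoid degenerated to a constant: unidentifiable
    converged = bool(best.success) and bool(c > 1e-8)
    return ArcFit(
        model="logistic3",
        response=response,
        params={"a": float(a), "b": float(b), "c": float(c)},
        r2=r2,
        df=n - 3,
        n_points=n,
        converged=converged,
        message="" if converged else "degenerate or non-converged sigmoid",
        ss_res=ss_res,
    )


def _logistic3_init(ages, y) -> np.ndarray:
    a0 = 1.05 * float(np.max(y))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log((a0 - y) / y)
    ok = np.isfinite(z)
    if ok.sum() >= 2 and np.ptp(ages[ok]) > 0:
        slope = np.polyfit(ages[ok], z[ok], 1)[0]
        c0 = max(-slope, 1e-3)
    else:
        c0 = 1.0
    i_min = int(np.argmin(ages))
    y_min = float(np.clip(y[i_min], 1e-6 * a0, a0 * (1 - 1e-6)))
    b0 = max((a0 / y_min - 1.0) * math.exp(c0 * ages[i_min]), 1e-6)
    return np.array([a0, b0, c0])


def compare_models(lin: ArcFit, log3: ArcFit) -> dict:
    """Compare a linear and a logistic fit of the same response.

    The primary criterion is r² (the larger wins); Gaussian AIC is reported
    as a secondary criterion.  Exact r² ties yield no preference.
    """
    if lin.n_points != log3.n_points:
        raise ValueError("fits are not on the same number of points")
    if lin.response != log3.response:
        raise ValueError("fits are not of the same response")
    if math.isclose(lin.r2, log3.r2, rel_tol=0, abs_tol=1e-12):
        preferred = None
    else:
        preferred = "linear" if lin.r2 > log3.r2 else "logistic3"
    return {
        "response": lin.response,
        "r2_linear": lin.r2,
        "r2_logistic3": log3.r2,
        "aic_linear": lin.aic(),
        "aic_logistic3": log3.aic(),
        "preferred": preferred,
        "preferred_by_aic": (
            None
            if math.isclose(lin.aic(), log3.aic(), rel_tol=0, abs_tol=1e-12)
            else ("linear" if lin.aic() < log3.aic() else "logistic3")
        ),
    }


def apply_lumping(
    tree: DatedTree,
    ranges: dict[str, RangeGeom],
    lumping: dict[str, str],
) -> tuple[DatedTree, dict[str, RangeGeom]]:
    """Merge tips into taxonomic groups: union ranges, prune the tree.

    ``lumping`` maps taxon_id -> group_id (tips absent from the map keep
    their identity).  Each group's tips must form a clade; the tree keeps
    one tip per group, placed at the group's crown position, and the group's
    range is the union of the members' ranges.  Groups whose members span
    the two daughter clades of a retained node are rejected.
    """
    groups: dict[str, set[str]] = {}
    for tip, grp in lumping.items():
        groups.setdefault(grp, set()).add(tip)

    # independent copy via newick round-trip so taxon labels can be rewritten
    newick = tree.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    tree2 = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        rooting="force-rooted",
    )
    dt = validate_tree(tree2)
    label_to_leaf = {leaf.taxon.label: leaf for leaf in tree2.leaf_nodes()}
    for grp, members in sorted(groups.items()):
        missing = members - set(label_to_leaf)
        if missing:
            raise KeyError(f"lumping group {grp!r}: unknown tips {sorted(missing)}")
        if len(members) == 1:
            (only,) = members
            label_to_leaf[only].taxon.label = grp
            continue
        mrca = tree2.mrca(taxa=[label_to_leaf[m].taxon for m in members])
        clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if clade != members:
            raise ValueError(
                f"lumping group {grp!r} is not a clade: its ancestor also "
                f"contains {sorted(clade - members)}"
            )
        # collapse the clade to a single tip at age 0 under the mrca's parent
        parent = mrca.parent_node
        keep = label_to_leaf[sorted(members)[0]]
        taxon = keep.taxon
        taxon.label = grp
        new_leaf = dendropy.Node(taxon=taxon)
        if parent is None:
            raise ValueError(f"lumping group {grp!r} covers the whole tree")
        edge_len = mrca.edge.length + dt.ages[mrca]
        parent.remove_child(mrca)
        parent.add_child(new_leaf)
        new_leaf.edge.length = edge_len
        label_to_leaf = {leaf.taxon.label: leaf for leaf in tree2.leaf_nodes()}
    lumped_tree = validate_tree(tree2)

    new_ranges: dict[str, RangeGeom] = {}
    lumped = set(lumping)
    for taxon, rg in ranges.items():
        if taxon not in lumped:
            new_ranges[taxon] = rg
    for grp, members in groups.items():
        member_ranges = [ranges[m] for m in sorted(members) if m in ranges]
        if member_ranges:
            new_ranges[grp] = union_range(member_ranges, taxon_id=grp)
    return lumped_tree, new_ranges


def build_arc_table(
    tree: DatedTree,
    ranges: dict[str, RangeGeom],
    lumping: dict[str, str] | None = None,
    include_root: bool = True,
) -> list[NodeRecord]:
    """Complete the node table: clade ranges, indexes, species sympatry.

    Clade ranges are unions of member-species ranges.  Lumping (optional)
    merges named tips before anything is computed; clade-level sympatry at
    nodes above the lump is unaffected, while species-level mean/max
    sympatry generally changes.
    """
    if lumping:
        tree, ranges = apply_lumping(tree, ranges, lumping)
    tips = set(tree.tip_labels())
    missing = tips - set(ranges)
    if missing:
        raise KeyError(f"no range for tips {sorted(missing)}")
    records = node_table(tree, include_root=include_root)
    clade_cache: dict[frozenset, RangeGeom] = {}

    def clade_range(tip_set: frozenset) -> RangeGeom:
        if tip_set not in clade_cache:
            clade_cache[tip_set] = union_range(
                [ranges[t] for t in sorted(tip_set)]
            )
        return clade_cache[tip_set]

    for rec in records:
        left = clade_range(rec.tips_left)
        right = clade_range(rec.tips_right)
        rec.area_left = left.area
        rec.area_right = right.area
        rec.overlap = overlap_area(left, right)
        rec.sympatry = sympatry_index(left, right)
        rec.symmetry = symmetry_index(left, right)
        rec.mean_sp_sympatry, rec.max_sp_sympatry = species_pair_sympatry(
            rec, ranges
        )
    return records
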