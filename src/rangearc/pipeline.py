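"""End-to-end analysis runs: ranges + tree -> node table -> fits -> DEC.

Each ``run_*`` function is deterministic for a fixed config and seed, and
writes diffable text outputs (TSV/JSON/newick, floats at 6 significant
digits) into an output directory together with an echo of its config.
"""

from __future__ import annotations

import json
from pathlib import Path

from rangearc import synthetic_data
from rangearc.arc_stats import (
    arcsine_transform,
    build_arc_table,
    compare_models,
    fit_linear,
    fit_logistic3,
)
from rangearc.dec_model import (
    ancestral_splits,
    fit_dec,
    read_coding_tsv,
    state_label,
    write_coding_tsv,
)
from rangearc.phylo_io import internal_node_ids, read_tree
from rangearc.range_geometry import load_ranges, write_geojson

__all__ = ["run_arc", "run_dec", "run_simulate", "run_fixture"]


def _g(x) -> str:
    return f"{x:.6g}"


def _np_safe(o):
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=_np_safe) + "\n"
    )


def _echo_config(out_dir: Path, **config) -> None:
    _write_json({k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
                out_dir / "config.json")


NODE_TABLE_COLUMNS = [
    "node_id", "age_ma", "clade_a_tips", "clade_b_tips", "area_a_km2",
    "area_b_km2", "overlap_km2", "sympatry", "symmetry", "mean_sp_sympatry",
    "max_sp_sympatry", "asin_sympatry", "asin_symmetry",
    "asin_mean_sp_sympatry", "asin_max_sp_sympatry",
]


def run_arc(
    tree_path,
    ranges_path,
    out_dir,
    lump_path=None,
    include_root: bool = True,
    arcsine: str = "sqrt",
    ranges_format: str = "geojson",
    seed: int = 0,
) -> dict:
    """The full age-range-correlation analysis.

    Produces ``node_table.tsv`` (one row per internal node with areas,
    overlap, indexes and their arcsine transforms) and ``fits.json`` with
    the seven regressions: node / mean-species / max-species sympatry each
    linear and logistic, plus the symmetry linear fit, and the
    linear-vs-logistic model comparison per sympatry response.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = read_tree(tree_path)
    ranges = load_ranges(ranges_path, fmt=ranges_format)
    lumping = _read_lumping(lump_path) if lump_path else None

    tips = set(tree.tip_labels())
    known = set(ranges) | (set(lumping) if lumping else set())
    if not lumping:
        extra_r = set(ranges) - tips
        missing_r = tips - set(ranges)
        if extra_r or missing_r:
            raise ValueError(
                "tree tips and range taxa differ: "
                f"tips without range {sorted(missing_r)}, "
                f"ranges without tip {sorted(extra_r)}"
            )

    records = build_arc_table(
        tree, ranges, lumping=lumping, include_root=include_root
    )
    rows = []
    for r in records:
        rows.append({
            "node_id": r.node_id,
            "age_ma": _g(r.age),
            "clade_a_tips": ";".join(sorted(r.tips_left)),
            "clade_b_tips": ";".join(sorted(r.tips_right)),
            "area_a_km2": _g(r.area_left),
            "area_b_km2": _g(r.area_right),
            "overlap_km2": _g(r.overlap),
            "sympatry": _g(r.sympatry),
            "symmetry": _g(r.symmetry),
            "mean_sp_sympatry": _g(r.mean_sp_sympatry),
            "max_sp_sympatry": _g(r.max_sp_sympatry),
            "asin_sympatry": _g(arcsine_transform(r.sympatry, variant=arcsine)),
            "asin_symmetry": _g(
                arcsine_transform(r.symmetry, kind="symmetry", variant=arcsine)
            ),
            "asin_mean_sp_sympatry": _g(
                arcsine_transform(r.mean_sp_sympatry, variant=arcsine)
            ),
            "asin_max_sp_sympatry": _g(
                arcsine_transform(r.max_sp_sympatry, variant=arcsine)
            ),
        })
    with open(out_dir / "node_table.tsv", "w") as fh:
        fh.write("\t".join(NODE_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in NODE_TABLE_COLUMNS) + "\n")

    ages = [r.age for r in records]
    fits: dict = {}
    for response, col in [
        ("node_sympatry", "sympatry"),
        ("mean_species_sympatry", "mean_sp_sympatry"),
        ("max_species_sympatry", "max_sp_sympatry"),
    ]:
        y = [
            arcsine_transform(getattr(r, col), variant=arcsine) for r in records
        ]
        lin = fit_linear(ages, y, response=response)
        log3 = fit_logistic3(ages, y, response=response, seed=seed)
        fits[response] = {
            "linear": _fit_dict(lin),
            "logistic3": _fit_dict(log3),
            "comparison": compare_models(lin, log3),
        }
    y_symm = [
        arcsine_transform(r.symmetry, kind="symmetry", variant=arcsine)
        for r in records
    ]
    symm_lin = fit_linear(ages, y_symm, response="symmetry")
    import numpy as np

    raw_symm = [r.symmetry for r in records]
    fits["symmetry"] = {
        "linear": _fit_dict(symm_lin),
        "mean_raw": float(np.mean(raw_symm)),
        "sd_raw": float(np.std(raw_symm, ddof=1)),
        "mean_transformed": float(np.mean(y_symm)),
        "sd_transformed": float(np.std(y_symm, ddof=1)),
    }
    _write_json(fits, out_dir / "fits.json")
    _echo_config(
        out_dir,
        command="arc", tree=tree_path, ranges=ranges_path, lump=lump_path,
        include_root=include_root, arcsine=arcsine,
        ranges_format=ranges_format, seed=seed,
    )
    return {"node_table": rows, "fits": fits}


def _fit_dict(f) -> dict:
    d = {
        "model": f.model,
        "response": f.response,
        "params": {k: float(v) for k, v in f.params.items()},
        "r2": f.r2,
        "df": f.df,
        "n_points": f.n_points,
        "aic": f.aic(),
        "converged": f.converged,
    }
    if f.p_slope is not None:
        d["p_slope"] = f.p_slope
        d["p_intercept"] = f.p_intercept
    if f.message:
        d["message"] = f.message
    return d


def _read_lumping(path) -> dict[str, str]:
    lumping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "taxon_id\tgroup_id":
                continue
            taxon, group = line.split("\t")
            lumping[taxon] = group
    return lumping


def run_dec(tree_path, coding_path, out_dir, root_prior=None) -> dict:
    """Fit DEC rates by ML and reconstruct ancestral range splits.

    Writes ``dec_model.json`` (rates, log-likelihood), ``dec_splits.tsv``
    (per node the ranked split scenarios, slash notation
    upper-daughter/lower-daughter), and ``annotated.nwk`` with each internal
    node labelled by its most probable scenario.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = read_tree(tree_path)
    coding = read_coding_tsv(coding_path)
    model = fit_dec(tree, coding, root_prior=root_prior)
    rec = ancestral_splits(tree, coding, model)

    _write_json(
        {
            "areas": model.areas,
            "dispersal_rate": model.d,
            "extinction_rate": model.e,
            **model.fit_info,
        },
        out_dir / "dec_model.json",
    )
    with open(out_dir / "dec_splits.tsv", "w") as fh:
        fh.write("node_id\trank\tupper\tlower\trel_likelihood\ttie\n")
        for node_id in rec.scenarios:
            for rank, (L, R, p) in enumerate(rec.scenarios[node_id], 1):
                fh.write(
                    f"{node_id}\t{rank}\t{state_label(L, model.areas)}\t"
                    f"{state_label(R, model.areas)}\t{_g(p)}\t"
                    f"{int(rec.ties[node_id])}\n"
                )

    ids = internal_node_ids(tree)
    for node, node_id in ids.items():
        node.label = rec.slash_label(node_id)
    (out_dir / "annotated.nwk").write_text(tree.as_newick() + "\n")
    _echo_config(out_dir, command="dec", tree=tree_path, coding=coding_path)
    return {"model": model, "splits": rec}


def run_simulate(mode: str, n_tips: int, seed: int, out_dir) -> dict:
    """Simulate one dataset under a speciation mode and write it out.

    The tree is generated from the seed before range evolution, so two
    modes run with the same seed share the topology and node ages and
    differ only in geometries.  Files: ``tree.nwk``, ``ranges.geojson``,
    ``coding.tsv`` (a DEC forward simulation on the same tree) and
    ``truth.json`` (per-node split truth).
    """
    from rangearc.dec_model import DecModel

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.mode_config(mode, seed=seed, n_tips=n_tips)
    tree = synthetic_data.simulate_yule_tree(
        n_tips, cfg.speciation_rate, seed=seed
    )
    out = synthetic_data.evolve_ranges(tree, cfg=cfg)
    dec_truth_model = DecModel(["W", "C", "H", "E"], d=0.05, e=0.01)
    coding, dec_truth = synthetic_data.simulate_dec_history(
        tree, dec_truth_model, seed=seed
    )
    (out_dir / "tree.nwk").write_text(tree.as_newick() + "\n")
    write_geojson(out.ranges, out_dir / "ranges.geojson")
    write_coding_tsv(coding, out_dir / "coding.tsv")
    truth = {
        "split_truth": out.truth,
        "dec_truth": {k: sorted(v) for k, v in dec_truth.items()},
    }
    _write_json(truth, out_dir / "truth.json")
    _echo_config(out_dir, command="simulate", mode=mode, n_tips=n_tips, seed=seed)
    return {"tree": tree, "ranges": out.ranges, "coding": coding, "truth": truth}


def run_fixture(out_dir) -> dict:
    """Write the packaged accentor-like fixture (tree, ranges, coding)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = synthetic_data.make_prunellid_fixture()
    (out_dir / "tree.nwk").write_text(fx.tree.as_newick() + "\n")
    write_geojson(fx.ranges, out_dir / "ranges.geojson")
    write_coding_tsv(fx.coding, out_dir / "coding.tsv")
    _echo_config(out_dir, command="fixture")
    return {"tree": fx.tree, "ranges": fx.ranges, "coding": fx.coding}
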