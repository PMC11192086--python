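"""End-to-end analysis pipeline with cached stage artifacts.

Stages (in dependency order): enumerate -> evaluate -> bayes -> gpn ->
embed -> behavior -> motifs.  Each stage consumes the artifacts of its
prerequisites from a shared context and contributes its own; the final
report collects the headline counts (programs per size, good programs,
GPN membership, key/sloppy mutation counts, distinguishability
thresholds, subgroup sizes, motif counts) together with the provenance
needed to reproduce them.  A rerun with the same config produces an
identical report: no timestamps, no hidden randomness beyond the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .bayes import default_alpha_grid, structurally_bayesian_set
from .embedding import (
    behavioral_tree,
    build_gpn,
    mutation_graph,
    performance_tree,
    write_gexf,
)
from .enumeration import enumerate_all_up_to, raw_space_size
from .evaluation import (
    random_policy_rate,
    sequence_distribution,
    wslg_reward_rate,
)
from .motifs import (
    behavioral_similarity,
    cluster_subgroups,
    confusion_matrix,
    distinguishability_thresholds,
    motif_statistics,
    program_motifs,
    sequence_distinguishability,
)
from .task import TaskParams

__all__ = ["STAGES", "run_pipeline"]

STAGES = ("enumerate", "evaluate", "bayes", "gpn", "embed", "behavior", "motifs")

_PREREQ = {
    "enumerate": (),
    "evaluate": ("enumerate",),
    "bayes": (),
    "gpn": ("evaluate",),
    "embed": ("gpn",),
    "behavior": ("gpn", "bayes"),
    "motifs": ("behavior",),
}


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages and return the report dictionary.

    Config keys: ``stages`` (default all), ``max_states`` (default 3),
    ``ell`` (default 10), ``seed`` (required when behavior/motifs run),
    task parameters under ``mean_reward``/``contrast``/``hazard``, and
    ``alpha_grid`` as [start, stop, step].
    """
    stages = list(config.get("stages", STAGES))
    for st in stages:
        for pre in _PREREQ[st]:
            if pre not in stages:
                raise ValueError(
                    f"stage '{st}' requires stage '{pre}' to run first; "
                    f"add '{pre}' to the stage list"
                )
    stages = [s for s in STAGES if s in stages]
    params = TaskParams(
        mean_reward=float(config.get("mean_reward", 0.3)),
        contrast=float(config.get("contrast", -0.5)),
        hazard=float(config.get("hazard", 0.05)),
    )
    m_max = int(config.get("max_states", 3))
    ell = int(config.get("ell", 10))
    if any(s in stages for s in ("behavior", "motifs")) and "seed" not in config:
        raise ValueError("a 'seed' is required when behavior/motifs stages run")
    seed = int(config.get("seed", 0))
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    ctx: dict = {}
    report: dict = {
        "config": {
            "stages": stages,
            "max_states": m_max,
            "ell": ell,
            "seed": seed,
            "params": params.to_dict(),
        },
        "code_version": __version__,
    }

    if "enumerate" in stages:
        ens = enumerate_all_up_to(m_max, params)
        ctx["ensemble"] = ens
        report["enumeration"] = {
            "counts_per_size": ens.size_counts(),
            "raw_space_per_size": {
                m: raw_space_size(m) for m in range(2, m_max + 1)
            },
            "total": len(ens),
        }

    if "evaluate" in stages:
        ens = ctx["ensemble"]
        ens.evaluate()
        ens.sort()
        best = int(np.argmax(ens.reward_rates))
        report["evaluation"] = {
            "wslg_rate": wslg_reward_rate(params),
            "random_rate": random_policy_rate(params),
            "n_good": int(ens.flags["good"].sum()),
            "n_low_performing": int(ens.flags["low_performing"].sum()),
            "best_id": ens[best].canonical_id,
            "best_rate": float(ens.reward_rates[best]),
        }
        if outdir is not None:
            from .io import write_ensemble

            write_ensemble(ens, outdir / "ensemble.jsonl")

    if "bayes" in stages:
        grid_cfg = config.get("alpha_grid")
        grid = (
            np.arange(grid_cfg[0], grid_cfg[1] + 1e-12, grid_cfg[2])
            if grid_cfg
            else default_alpha_grid()
        )
        sb = structurally_bayesian_set(params, m_max=m_max, alpha_grid=grid)
        ctx["sb"] = sb
        report["bayes"] = {"n_structurally_bayesian": len(sb)}
        if "ensemble" in ctx and ctx["ensemble"].flags.get("good") is not None:
            good_ids = {
                p.canonical_id
                for p, g in zip(ctx["ensemble"], ctx["ensemble"].flags["good"])
                if g
            }
            report["bayes"]["n_structurally_bayesian_good"] = sum(
                1 for p in sb if p.canonical_id in good_ids
            )

    if "gpn" in stages:
        ens = ctx["ensemble"]
        graph = mutation_graph(ens)
        ctx["graph"] = graph
        gpn = build_gpn(ens, graph)
        ctx["gpn"] = gpn
        report["gpn"] = {
            "size": len(gpn.ensemble),
            "n_good": gpn.n_good,
            "n_connection": gpn.n_connection,
            "n_low_performing": gpn.n_low_performing,
            "unconnected_components": gpn.unconnected_components,
        }

    if "embed" in stages:
        ens = ctx["ensemble"]
        tree = performance_tree(ens, ctx["graph"])
        ctx["performance_tree"] = tree
        report["embed"] = {
            "root": tree.roots[0],
            "unattached": tree.n_unattached,
        }
        if outdir is not None:
            write_gexf(tree, outdir / "performance_tree.gexf")

    if "behavior" in stages:
        gpn = ctx["gpn"]
        sb_ids = {p.canonical_id for p in ctx["sb"]}
        members = gpn.ensemble
        dist10 = [sequence_distribution(p, params, ell) for p in members]
        by_ell = {ell: dist10}
        cur = dist10
        for l2 in range(ell - 1, 0, -1):
            cur = [d.marginalize() for d in cur]
            by_ell[l2] = cur
        ctx["dists"] = dist10
        b = behavioral_similarity(by_ell, members.ids)
        ctx["similarity"] = b
        gsub = gpn.graph
        btree = behavioral_tree(gpn, b, b_max=ell, graph=gsub)
        ctx["behavioral_tree"] = btree
        kinds = list(btree.edge_kind.values())
        sb_mask = np.array([pid in sb_ids for pid in members.ids])
        labels = distinguishability_thresholds(
            dist10, sb_mask, exclude_mask=members.flags.get("low_performing")
        )
        ctx["labels"] = labels
        selected = labels.globally_distinguishable & ~labels.behaviorally_bayesian
        ctx["selected"] = selected
        sub_labels = np.full(len(members), -1)
        if selected.sum() >= 2:
            cm = confusion_matrix(
                [d for d, s in zip(dist10, selected) if s],
                [pid for pid, s in zip(members.ids, selected) if s],
            )
            sub_labels[np.flatnonzero(selected)] = cluster_subgroups(
                cm.matrix, seed=seed
            )
        ctx["subgroups"] = sub_labels
        uniq, cnt = np.unique(sub_labels[sub_labels >= 0], return_counts=True)
        report["behavior"] = {
            "n_key_edges": kinds.count("key"),
            "n_sloppy_edges": kinds.count("sloppy"),
            "c_star_gpn": labels.c_star_gpn,
            "c_star_sb": labels.c_star_sb,
            "n_globally_distinguishable": int(
                labels.globally_distinguishable.sum()
            ),
            "n_behaviorally_bayesian": int(labels.behaviorally_bayesian.sum()),
            "n_selected_non_bayesian": int(selected.sum()),
            "n_subgroups": int(len(uniq)),
            "subgroup_sizes": {int(k): int(v) for k, v in zip(uniq, cnt)},
        }
        if outdir is not None:
            write_gexf(btree, outdir / "behavioral_tree.gexf")

    if "motifs" in stages:
        gpn = ctx["gpn"]
        members = gpn.ensemble
        dist10 = ctx["dists"]
        seq_dist = sequence_distinguishability(dist10)
        sets = [
            program_motifs(p, d, sd)
            for p, d, sd in zip(members, dist10, seq_dist)
        ]
        ctx["motif_sets"] = sets
        sb_ids = {p.canonical_id for p in ctx["sb"]}
        sb_motifs = sorted(
            {m for ms in sets if ms.program_id in sb_ids for m in ms.motifs}
        )
        sel = ctx["selected"]
        sel_motifs = sorted(
            {m for ms, s in zip(sets, sel) if s for m in ms.motifs}
        )
        extra = [m for m in sel_motifs if m not in sb_motifs]
        report["motifs"] = {
            "n_motifs_total": len({m for ms in sets for m in ms.motifs}),
            "n_bayesian_motifs": len(sb_motifs),
            "n_non_bayesian_motifs_selected": len(extra),
        }
        if sel.sum() >= 2 and (ctx["subgroups"] >= 0).sum() >= 2:
            sel_sets = [ms for ms, s in zip(sets, sel) if s]
            sel_groups = ctx["subgroups"][np.flatnonzero(sel)]
            stats = motif_statistics(sel_sets, sel_groups)
            ctx["motif_stats"] = stats

    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    report["_context"] = ctx
    return report
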