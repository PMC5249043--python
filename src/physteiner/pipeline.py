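"""End-to-end orchestration of the subnetwork-identification protocol.

One pipeline run generates (or loads) a drug-feature table with planted
subclasses, builds one complete DSN per terminal subclass, derives two sparse
DSNs from each (MST augmentation -> ``D_<label>_a``; two-threshold deletion
-> ``D_<label>_b``), identifies subnetworks with several PSIA runs plus one
GW run per sparse DSN, scores everything with the Rand Index against the
superclass (the union of all subclasses), and ranks out-of-superclass drugs
by how often they occur in the per-DSN best subnetworks.

All randomness derives from a single master seed; the manifest records every
derived seed so a run can be regenerated byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from physteiner.datagen import (
    DEFAULT_BLOCK_SIZES,
    generate_feature_table,
    load_class_membership,
    load_feature_table,
)
from physteiner.dsn import build_complete_dsn
from physteiner.errors import ParameterError
from physteiner.evaluate import candidate_frequencies, rand_index, select_best
from physteiner.gw import gw_identify
from physteiner.psia import PhysarumParams, psia_multi
from physteiner.sparsify import (
    SparsifyConfig,
    choose_thresholds,
    sparsify_mst_augment,
    sparsify_two_threshold,
)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Subclass label -> member count for the default synthetic study: nine
#: subclasses whose sizes match the terminal-set sizes of the reference
#: cardiovascular analysis.
DEFAULT_CLASSES: tuple[tuple[str, int], ...] = (
    ("C01", 22),
    ("C02", 12),
    ("C03", 13),
    ("C04", 4),
    ("C05", 9),
    ("C07", 15),
    ("C08", 8),
    ("C09", 16),
    ("C10", 8),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one full run.

    With ``feature_table_path`` unset, a synthetic table is generated from
    the generator settings. ``threshold_quantiles`` positions the
    two-threshold sparsifier's (t1, t2) at empirical quantiles of the
    complete graph's cost distribution, which adapts the deletion step to
    whatever cost scale the data produces; explicit ``t1``/``t2`` override
    the quantiles.
    """

    # data source
    feature_table_path: str | None = None
    membership_path: str | None = None
    n_drugs: int = 548
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    classes: tuple[tuple[str, int], ...] = DEFAULT_CLASSES
    within_class_feature_rate: float = 0.9
    background_rate: float | tuple[float, float] = (0.1, 0.4)
    shared_core_fraction: float = 0.05
    # which subclasses to iterate (None = all)
    subclasses: tuple[str, ...] | None = None
    # sparsifiers
    desired_edges: int = 1500
    add_probability: float = 0.5
    threshold_quantiles: tuple[float, float] = (0.95, 0.99)
    t1: float | None = None
    t2: float | None = None
    # solvers
    psia_params: PhysarumParams = field(default_factory=PhysarumParams)
    psia_runs: int = 3
    # bookkeeping
    candidate_threshold: int = 2
    master_seed: int = 0
    output_dir: str | None = None


def _derived_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([master, *path]).generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full protocol and return (and optionally write) the manifest.

    The manifest contains one row per (DSN, algorithm) pairing in the layout
    ID / |V| / |E| / |T| / T-Origin / Algorithm / |V'| / |E'| / I_c / RI,
    plus the candidate ranking and every derived seed.
    """
    if config.feature_table_path is not None:
        if config.membership_path is None:
            raise ParameterError("membership_path required with feature_table_path")
        table = load_feature_table(config.feature_table_path, config.block_sizes)
        membership = load_class_membership(config.membership_path)
    else:
        table, membership = generate_feature_table(
            n_drugs=config.n_drugs,
            block_sizes=config.block_sizes,
            classes=config.classes,
            within_class_feature_rate=config.within_class_feature_rate,
            background_rate=config.background_rate,
            shared_core_fraction=config.shared_core_fraction,
            seed=_derived_seed(config.master_seed, 0),
        )
    superclass = membership.superclass_set
    labels = (
        list(config.subclasses)
        if config.subclasses is not None
        else sorted(membership.subclass_sets)
    )

    rows: list[dict] = []
    seeds: dict[str, int] = {}
    selected_per_dsn: list = []
    for li, label in enumerate(labels):
        complete = build_complete_dsn(table, label, membership)
        if config.t1 is not None and config.t2 is not None:
            t1, t2 = config.t1, config.t2
        else:
            t1, t2 = choose_thresholds(complete, config.threshold_quantiles)
            t1 = config.t1 if config.t1 is not None else t1
            t2 = config.t2 if config.t2 is not None else t2
        sparse_seed = _derived_seed(config.master_seed, 1, li)
        seeds[f"sparsify/{label}"] = sparse_seed
        spar_cfg = SparsifyConfig(
            desired_edges=config.desired_edges,
            add_probability=config.add_probability,
            t1=t1,
            t2=t2,
            seed=sparse_seed,
        )
        dsns = {
            "a": sparsify_mst_augment(complete, spar_cfg),
            "b": sparsify_two_threshold(complete, spar_cfg),
        }
        for variant, dsn in dsns.items():
            dsn_id = f"D_{label}_{variant}"
            psia_seed = _derived_seed(config.master_seed, 2, li, ord(variant))
            gw_seed = _derived_seed(config.master_seed, 3, li, ord(variant))
            seeds[f"psia/{dsn_id}"] = psia_seed
            seeds[f"gw/{dsn_id}"] = gw_seed
            psia_subs = psia_multi(
                dsn, replace(config.psia_params, seed=psia_seed), config.psia_runs
            )
            gw_sub = gw_identify(dsn, gw_seed)
            best_psia = select_best(psia_subs, dsn, superclass)
            for algo, sub in (("PSIA", best_psia), ("GW", gw_sub)):
                res = rand_index(sub, dsn, superclass)
                rows.append(
                    {
                        "ID": dsn_id,
                        "|V|": dsn.n_vertices,
                        "|E|": dsn.n_edges,
                        "|T|": len(dsn.terminals),
                        "T-Origin": label,
                        "Algorithm": algo,
                        "|V'|": res.n_vertices,
                        "|E'|": res.n_edges,
                        "I_c": res.i_c,
                        "RI": round(res.rand_index, 1),
                        "objective": res.objective,
                    }
                )
            selected_per_dsn.append(
                (dsn_id, variant, select_best([best_psia, gw_sub], dsn, superclass))
            )

    # candidate mining over the best subnetwork of each second-type DSN
    selected_b = [sub for _, variant, sub in selected_per_dsn if variant == "b"]
    ranking = candidate_frequencies(
        selected_b or [sub for _, _, sub in selected_per_dsn],
        superclass,
        threshold=config.candidate_threshold,
    )
    manifest = {
        "config": _config_dict(config),
        "seeds": seeds,
        "results": rows,
        "candidates": [
            {"drug_id": d, "frequency": ranking.frequencies[d]}
            for d in ranking.candidates
        ],
        "frequencies": dict(sorted(ranking.frequencies.items())),
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            out / "results.tsv",
            ["ID", "|V|", "|E|", "|T|", "T-Origin", "Algorithm", "|V'|", "|E'|", "I_c", "RI"],
            rows,
        )
        _write_tsv(
            out / "candidates.tsv",
            ["drug_id", "frequency"],
            manifest["candidates"],
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["psia_params"] = asdict(config.psia_params)
    return d


def _write_tsv(path: Path, columns: Sequence[str], rows: Sequence[dict]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n")
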