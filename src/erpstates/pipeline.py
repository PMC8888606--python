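"""End-to-end orchestration: simulate/load -> per-ERP k selection -> group templates -> backfit -> metrics -> statistics.

A :class:`PipelineConfig` fully determines a run; the effective config is
dumped next to every output and reruns with an identical config + seed are
reproducible bit-for-bit.  Global templates are canonically ordered by total
cohort coverage after backfitting (descending) and labelled M1..Mk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .backfit import MicrostateSequence, backfit, build_metrics_table
from .exceptions import InvalidInputError
from .group import GlobalTemplateSet, cluster_group, pool_subject_templates
from .model_selection import KL_RULES, select_k_for_erp
from .simulate import SyntheticSpec, lateralized_effects_spec, make_cohort
from .stats import run_battery
from .topography import ErpEpoch, apply_average_reference, crop_window

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("erpstates.pipeline")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    With ``input_dir`` unset, a synthetic cohort is generated from
    ``synthetic`` (a :class:`SyntheticSpec` field mapping).  ``kl_rule``
    applies to subject-level selection, ``group_kl_rule`` (default: same) to
    the second-level clustering.
    """

    seed: int = 0
    input_dir: str | None = None
    window_ms: tuple[float, float] = (0.0, 400.0)
    k_min: int = 1
    k_max: int = 12
    kl_rule: str = "second_max"
    group_kl_rule: str | None = None
    n_restarts: int = 64
    group_restarts: int | None = None
    max_iter: int = 300
    tol: float = 1e-7
    min_duration_ms: float = 0.0
    run_statistics: bool = True
    synthetic: dict = field(default_factory=dict)
    synthetic_effects_preset: bool = False

    def __post_init__(self) -> None:
        if self.kl_rule not in KL_RULES:
            raise InvalidInputError(f"kl_rule must be one of {KL_RULES}")
        if self.group_kl_rule is not None and self.group_kl_rule not in KL_RULES:
            raise InvalidInputError(f"group_kl_rule must be one of {KL_RULES}")
        if self.k_max - self.k_min + 1 < 4:
            raise InvalidInputError(
                "k range too narrow for the KL criterion; use at least 4 k values "
                "(e.g. k_min=1, k_max=6)"
            )

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        if "window_ms" in raw:
            raw["window_ms"] = tuple(raw["window_ms"])
        synth = raw.get("synthetic")
        if synth and "conditions" in synth:  # YAML has no tuples
            synth["conditions"] = tuple(synth["conditions"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    global_templates: GlobalTemplateSet
    sequences: list[MicrostateSequence]
    metrics: pd.DataFrame
    subject_results: list
    statistics: dict[str, pd.DataFrame] | None = None
    handedness: dict[str, float] | None = None
    ground_truth: object = None  # GroundTruth for synthetic runs


def _load_inputs(config: PipelineConfig):
    if config.input_dir is None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        if config.synthetic_effects_preset:
            spec = lateralized_effects_spec(**spec_kwargs)
        else:
            spec = SyntheticSpec(**spec_kwargs)
        cohort = make_cohort(spec)
        return cohort.epochs, cohort.ground_truth, cohort.montage
    indir = Path(config.input_dir)
    stems = sorted(p.with_suffix("") for p in indir.glob("*.tsv") if p.stem != "montage")
    if not stems:
        raise InvalidInputError(f"no ERP matrices (*.tsv) found in {indir}")
    epochs = [eio.load_epoch(s) for s in stems]
    montage = None
    mpath = indir / "montage.tsv"
    if mpath.exists():
        montage = eio.load_montage(mpath)
    return epochs, None, montage


def run_pipeline(config: PipelineConfig, outdir: Path | str | None = None) -> PipelineResult:
    """Run all stages; write artifacts under ``outdir`` when given.

    Stage order: load/simulate -> average reference + window -> per-epoch KL
    k selection -> pool subject templates -> group clustering -> backfit ->
    metrics -> statistics battery.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_used.yaml").write_text(config.to_yaml())

    epochs, ground_truth, montage = _load_inputs(config)
    log.info("stage load: %d epochs", len(epochs))

    windowed: list[ErpEpoch] = []
    for e in epochs:
        e = apply_average_reference(e)
        windowed.append(crop_window(e, *config.window_ms))

    ss = np.random.SeedSequence(config.seed)
    epoch_seeds = ss.spawn(len(windowed) + 1)
    subject_results = []
    kl_rows = []
    for i, epoch in enumerate(windowed):
        try:
            curve, res = select_k_for_erp(
                epoch,
                config.k_range,
                rule=config.kl_rule,
                n_restarts=config.n_restarts,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=int(epoch_seeds[i].generate_state(1)[0] % (2**31)),
            )
        except Exception as exc:
            raise type(exc)(
                f"stage select-k failed for subject={epoch.subject!r} "
                f"condition={epoch.condition!r}: {exc}"
            ) from exc
        subject_results.append(res)
        t = curve.as_table()
        t.insert(0, "subject", epoch.subject)
        t.insert(1, "condition", epoch.condition)
        kl_rows.append(t)
        if (i + 1) % 16 == 0 or i + 1 == len(windowed):
            log.info("stage select-k: %d/%d epochs", i + 1, len(windowed))
    kl_table = pd.concat(kl_rows, ignore_index=True)

    pooled, provenance = pool_subject_templates(subject_results)
    log.info("stage pool: %d subject-level maps", pooled.shape[0])

    group_rule = config.group_kl_rule or config.kl_rule
    gts = cluster_group(
        pooled,
        config.k_range,
        rule=group_rule,
        n_restarts=config.group_restarts or config.n_restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=int(epoch_seeds[-1].generate_state(1)[0] % (2**31)),
        montage_ref=subject_results[0].montage_ref,
    )
    log.info("stage group: k_global=%d", gts.k_global)

    sequences = [
        backfit(e, gts, min_duration_ms=config.min_duration_ms) for e in windowed
    ]
    # canonical ordering: descending total coverage across the cohort
    counts = np.zeros(gts.k_global)
    for seq in sequences:
        for cls in range(gts.k_global):
            counts[cls] += int(np.sum(seq.labels == cls))
    order = list(np.argsort(-counts, kind="stable"))
    gts = gts.reordered(order)
    relabel = {old: new for new, old in enumerate(order)}
    for seq in sequences:
        seq.labels = np.array([relabel.get(l, -1) for l in seq.labels])
    log.info("stage backfit: %d sequences, coverage order %s", len(sequences), order)

    metrics = build_metrics_table(sequences, gts.k_global, gts.names)

    statistics = None
    handedness = ground_truth.handedness if ground_truth is not None else None
    if config.run_statistics:
        statistics = run_battery(metrics, handedness)
        log.info(
            "stage statistics: %d ANOVA rows, %d skipped",
            len(statistics["anovas"]),
            len(statistics["skipped"]),
        )

    if out is not None:
        if montage is not None:
            eio.save_montage(out / "montage.tsv", montage)
        kl_table.to_csv(out / "kl_curves.tsv", sep="\t", index=False, float_format="%.10g")
        eio.save_templates(out / "global_templates", gts)
        seqdir = out / "sequences"
        seqdir.mkdir(exist_ok=True)
        for seq in sequences:
            eio.save_sequence(seqdir / f"{seq.subject}_{seq.condition}.tsv", seq)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        if statistics is not None:
            for name, df in statistics.items():
                df.to_csv(out / f"stats_{name}.csv", index=False, float_format="%.10g")

    result = PipelineResult(
        config=config,
        global_templates=gts,
        sequences=sequences,
        metrics=metrics,
        subject_results=subject_results,
        statistics=statistics,
        handedness=handedness,
    )
    result.ground_truth = ground_truth
    return result
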