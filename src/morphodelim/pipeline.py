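"""Orchestration of the full delimitation workflow.

The workflow follows the two-phase logic of exploratory hypothesis formation
followed by confirmatory testing: read measurements → remove allometric
variance → cluster nest centroids (PART for the cluster number, UPGMA/Ward
dendrograms, optional NMDS) → feed the exploratory clusters as candidate
species labels into a cross-validated LDA → evaluate wild-card specimens and
numeric keys.  Exploratory labels enter the confirmatory stage only when
``auto_confirm`` is set (or after the caller inspects the partition),
keeping the hypothesis-then-test separation explicit.

All stages derive their seeds from one master seed; a fixed config + seed
reproduces a byte-identical report payload.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BS_GYNE,
    BS_WORKER,
    SC_WORKER,
    CharacterSystem,
    Dataset,
    MorphometryError,
    read_morphometry_table,
)
from .rav import (
    CorrectedMatrix,
    RAVModel,
    apply_nestwise_residuals,
    apply_rav_index,
    fit_rav_index,
    fit_rav_nestwise,
    load_published_rav,
)
from .clustering import (
    Partition,
    agglomerate,
    compare_partitions,
    euclidean_distances,
    kmeans_partition,
    nmds,
    part,
)
from .ordination import pca, project
from .discriminant import (
    DiscriminantFunction,
    backward_stepwise,
    fit_lda,
    loo_crossvalidate,
    published_keys,
    score,
    wildcard_classify,
)

__all__ = ["RunConfig", "Report", "run_delimitation", "evaluate_types"]

_SYSTEMS = {
    ("BS", "worker"): BS_WORKER,
    ("BS", "gyne"): BS_GYNE,
    ("SC", "worker"): SC_WORKER,
}


@dataclass
class RunConfig:
    """Configuration of one delimitation run.

    ``rav`` selects the correction: ``"published"`` (packaged index
    constants, BS), ``"index"`` (fit from species labels in the data),
    ``"nestwise"`` (fit residual lines per nest, SC), or ``"none"``.
    """

    input_path: Optional[str] = None
    dataset: Optional[Dataset] = None
    system: str = "BS"
    caste: str = "worker"
    rav: str = "published"
    cluster_base: str = "kmeans"
    b: int = 1000
    min_size: int = 5
    k_max: int = 5
    standardize: bool = True
    run_nmds: bool = False
    pca_scale: bool = False
    lda_priors: str = "equal"
    stepwise_k: Optional[int] = None
    wildcards: tuple[str, ...] = ()
    auto_confirm: bool = True
    min_nest_n: int = 1
    seed: int = 0

    def resolve_system(self) -> CharacterSystem:
        if isinstance(self.system, CharacterSystem):
            return self.system
        key = (self.system, self.caste)
        if key not in _SYSTEMS:
            raise MorphometryError(f"no packaged character system for {key}")
        return _SYSTEMS[key]


@dataclass
class Report:
    """All results of one run plus the fitted objects needed to reuse them."""

    config: RunConfig
    dataset: Dataset
    rav_model: Optional[RAVModel]
    corrected: Optional[CorrectedMatrix]
    centroid_features: Optional[pd.DataFrame]
    partition: Optional[Partition]
    kmeans_agreement: Optional[dict]
    newick: dict[str, str]
    pca_scores: Optional[pd.DataFrame]
    pca_result: Optional[object]
    nmds_stress: Optional[float]
    specimen_labels: Optional[dict[str, str]]
    lda_features: Optional[pd.DataFrame]
    discriminant: Optional[DiscriminantFunction]
    confusion: Optional[pd.DataFrame]
    percent_correct: Optional[dict]
    stepwise_key: Optional[DiscriminantFunction]
    wildcard_posteriors: Optional[pd.DataFrame]
    log: list[str] = field(default_factory=list)

    def payload(self) -> dict:
        """Deterministic JSON-serializable summary of the run."""
        def df(x):
            return None if x is None else json.loads(x.to_json(orient="index"))

        return {
            "provenance": {
                "seed": self.config.seed,
                "system": str(self.config.system),
                "caste": self.config.caste,
                "rav": self.config.rav,
                "cluster_base": self.config.cluster_base,
                "b": self.config.b,
                "min_size": self.config.min_size,
                "n_records": len(self.dataset.records),
            },
            "partition": None if self.partition is None else {
                "k": self.partition.k, "labels": self.partition.labels,
            },
            "kmeans_agreement": self.kmeans_agreement,
            "newick": self.newick,
            "pca_scores": df(self.pca_scores),
            "nmds_stress": self.nmds_stress,
            "specimen_labels": self.specimen_labels,
            "confusion": df(self.confusion),
            "percent_correct": self.percent_correct,
            "discriminant": None if self.discriminant is None
            else json.loads(self.discriminant.to_json()),
            "stepwise_key": None if self.stepwise_key is None
            else json.loads(self.stepwise_key.to_json()),
            "wildcard_posteriors": df(self.wildcard_posteriors),
            "log": self.log,
        }

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.payload(), indent=2, sort_keys=True)
        )
        if self.partition is not None:
            self.partition.to_frame().to_csv(out / "partition.csv", index=False)
        for name, nwk in self.newick.items():
            (out / f"dendrogram_{name}.newick").write_text(nwk + "\n")
        if self.pca_scores is not None:
            self.pca_scores.to_csv(out / "pca_scores.csv")
        if self.confusion is not None:
            self.confusion.to_csv(out / "confusion.csv")
        if self.wildcard_posteriors is not None:
            self.wildcard_posteriors.to_csv(out / "wildcard_posteriors.csv")


def _corrected_features(
    dataset: Dataset, config: RunConfig, log: list[str]
) -> tuple[Optional[RAVModel], Optional[CorrectedMatrix], pd.DataFrame]:
    """Per-specimen feature matrix for the exploratory stage."""
    system = dataset.system
    if config.rav == "published":
        model = load_published_rav(config.caste, "BS")
        corrected = apply_rav_index(dataset, model)
        feats = corrected.with_size_column()
    elif config.rav == "index":
        labels = dataset.species_labels()
        if not labels:
            raise MorphometryError(
                "rav='index' needs species labels in the data; use 'published'"
            )
        model = fit_rav_index(dataset)
        corrected = apply_rav_index(dataset, model)
        feats = corrected.with_size_column()
    elif config.rav == "nestwise":
        model = fit_rav_nestwise(dataset, size_char=system.size_character)
        corrected = apply_nestwise_residuals(dataset, model)
        feats = corrected.frame
    elif config.rav == "none":
        model, corrected = None, None
        chars = [c for c in system.characters]
        complete, bad = dataset.complete_records(chars)
        if bad:
            log.append(f"{len(bad)} record(s) incomplete on raw characters; excluded")
        feats = pd.DataFrame(
            {c: [r.get(c, system) for r in complete] for c in chars},
            index=[r.specimen_id for r in complete],
        )
    else:
        raise MorphometryError(f"unknown rav option {config.rav!r}")
    if corrected is not None and corrected.excluded:
        log.append(
            f"{len(corrected.excluded)} record(s) excluded from RAV: "
            f"{sorted(corrected.excluded)[:5]}"
        )
    return model, corrected, feats


def run_delimitation(config: RunConfig) -> Report:
    """Execute the configured stages in hypothesis-then-test order."""
    log: list[str] = []
    if config.dataset is not None:
        dataset = config.dataset
    elif config.input_path is not None:
        dataset = read_morphometry_table(config.input_path, config.resolve_system())
    else:
        raise MorphometryError("RunConfig needs either dataset or input_path")
    system = dataset.system

    wild_ids = set(config.wildcards)
    training = [r for r in dataset.records if r.specimen_id not in wild_ids]
    wild = [r for r in dataset.records if r.specimen_id in wild_ids]
    if wild_ids and not wild:
        log.append("no wild-card id matched any record")
    train_ds = dataclasses.replace(dataset, records=training)

    ss = np.random.SeedSequence(config.seed)
    seed_part, seed_nmds, seed_kmeans = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    rav_model, corrected, feats = _corrected_features(train_ds, config, log)

    nest_of = {r.specimen_id: r.nest_id for r in training}
    cent = feats.groupby([nest_of[i] for i in feats.index]).mean()
    cent = cent.sort_index()

    partition = None
    kmeans_agreement = None
    newick: dict[str, str] = {}
    nmds_stress = None
    if cent.shape[0] < 2:
        log.append("single nest: clustering skipped")
    else:
        dist = euclidean_distances(cent, standardize=config.standardize)
        newick["upgma"] = agglomerate(dist, "UPGMA").to_newick()
        newick["ward"] = agglomerate(dist, "Ward").to_newick()
        partition = part(
            cent if not config.standardize else _zscore(cent),
            base=config.cluster_base, b=config.b,
            min_size=config.min_size, seed=seed_part, k_max=config.k_max,
        )
        if partition.k >= 2:
            km = kmeans_partition(
                _zscore(cent) if config.standardize else cent,
                k=partition.k, seed=seed_kmeans,
            )
            rep = compare_partitions(km, {i: str(c) for i, c in partition.labels.items()})
            kmeans_agreement = {
                "n_items": rep.n_items, "n_disagreeing": rep.n_misassigned,
                "disagreeing": rep.misassigned,
            }
        if config.run_nmds:
            emb = nmds(dist, dims=2, seed=seed_nmds)
            nmds_stress = emb.stress

    # ordination over the corrected nest-centroid matrix (size column dropped)
    pca_result = None
    pca_scores = None
    if cent.shape[0] >= 2:
        orc = cent.drop(columns=[system.size_character], errors="ignore")
        pca_result = pca(orc, center=True, scale=config.pca_scale)
        pca_scores = pca_result.scores

    # confirmatory stage
    specimen_labels = None
    discriminant = None
    confusion = None
    percent_correct = None
    stepwise_key = None
    wildcard_posteriors = None
    if partition is not None and partition.k >= 2 and config.auto_confirm:
        cluster_of_nest = partition.labels
        specimen_labels = {
            r.specimen_id: f"C{cluster_of_nest[r.nest_id]}" for r in training
        }
        raw_chars = [c for c in system.characters]
        complete, bad = train_ds.complete_records(raw_chars)
        present = [c for c in raw_chars
                   if all(r.has(c, system) for r in train_ds.records)]
        if len(present) < len(raw_chars):
            log.append(
                f"LDA uses {len(present)} of {len(raw_chars)} characters "
                "(complete across all records)"
            )
        X = pd.DataFrame(
            {c: [r.get(c, system) for r in training] for c in present},
            index=[r.specimen_id for r in training],
        )
        y = {i: specimen_labels[i] for i in X.index}
        if partition.k == 2:
            try:
                discriminant = fit_lda(X, y, priors=config.lda_priors)
                cm = loo_crossvalidate(X, y, priors=config.lda_priors)
                confusion = cm.counts
                percent_correct = {
                    str(k): float(v) for k, v in cm.percent_correct.items()
                }
                if config.stepwise_k is not None:
                    stepwise_key = backward_stepwise(
                        X, y, target_k=config.stepwise_k, priors=config.lda_priors
                    )
                if wild:
                    Q = pd.DataFrame(
                        {c: [r.get(c, system) for r in wild] for c in present},
                        index=[r.specimen_id for r in wild],
                    )
                    wildcard_posteriors = wildcard_classify(
                        X, y, Q, priors=config.lda_priors
                    )
            except MorphometryError as exc:
                log.append(f"confirmatory stage skipped: {exc}")
        else:
            log.append(
                f"confirmatory two-class LDA skipped: partition has k={partition.k}"
            )

    return Report(
        config=config, dataset=dataset, rav_model=rav_model, corrected=corrected,
        centroid_features=cent, partition=partition,
        kmeans_agreement=kmeans_agreement, newick=newick,
        pca_scores=pca_scores, pca_result=pca_result, nmds_stress=nmds_stress,
        specimen_labels=specimen_labels, lda_features=None if specimen_labels is None
        else X, discriminant=discriminant, confusion=confusion,
        percent_correct=percent_correct, stepwise_key=stepwise_key,
        wildcard_posteriors=wildcard_posteriors, log=log,
    )


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    if (sd == 0).any():
        raise MorphometryError(
            f"constant column(s) {list(frame.columns[sd == 0])} cannot be standardized"
        )
    return (frame - frame.mean()) / sd


def evaluate_types(report: Report, type_table: Dataset) -> pd.DataFrame:
    """Place type specimens against a finished run.

    Per type specimen: projection onto the run's ordination, wild-card
    posterior probabilities against the run's labeled pool, and scores under
    the packaged numeric keys (where the required characters are present).
    Specimens lacking required characters are skipped with a reason column.
    """
    rows = []
    system = type_table.system if type_table.records else None
    for r in type_table.records:
        row: dict[str, object] = {"specimen_id": r.specimen_id, "skip_reason": ""}
        # ordination projection
        if report.pca_result is not None and report.corrected is not None:
            try:
                corr = (
                    apply_rav_index([r], report.rav_model, on_missing="error")
                    if report.rav_model is not None
                    and report.rav_model.method == "index_quotient"
                    else None
                )
                feats = corr.frame if corr is not None else None
                if feats is not None:
                    proj = project(report.pca_result, feats)
                    row["PC1"] = float(proj.iloc[0, 0])
                    if proj.shape[1] > 1:
                        row["PC2"] = float(proj.iloc[0, 1])
            except MorphometryError as exc:
                row["skip_reason"] = f"ordination: {exc}"
        # wild-card posterior
        if report.lda_features is not None and report.specimen_labels is not None:
            try:
                Q = pd.DataFrame(
                    {c: [r.get(c, system)] for c in report.lda_features.columns},
                    index=[r.specimen_id],
                )
                post = wildcard_classify(
                    report.lda_features, report.specimen_labels, Q,
                    priors=report.config.lda_priors,
                )
                for cls in post.columns:
                    row[f"p_{cls}"] = float(post.iloc[0][cls])
            except MorphometryError as exc:
                row["skip_reason"] = (str(row["skip_reason"]) + f" lda: {exc}").strip()
        # packaged keys
        for key in published_keys():
            try:
                row[f"score_{key.name}"] = score(key, r, system=system)
            except MorphometryError:
                pass
        rows.append(row)
    return pd.DataFrame(rows).set_index("specimen_id") if rows else pd.DataFrame(
        columns=["specimen_id"]
    ).set_index("specimen_id")
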