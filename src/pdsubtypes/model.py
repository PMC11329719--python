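"""Model/Results surface of the subtyping pipeline.

:class:`AtrophySubtypeModel` holds the data and configuration;
:meth:`~AtrophySubtypeModel.fit` runs harmonization, random-forest
proximity, classical MDS, average-linkage clustering and the validity-index
ensemble vote, returning an :class:`AtrophySubtypeResults` carrying the
cluster solution, diagnostics and a ``summary()``.  Characterization,
effect-size maps, transition analysis, longitudinal trajectories, per-cohort
validation and plotting hang off the results object.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize
from .cluster import (average_linkage, classical_mds, cut_tree,
                      proximity_to_dissimilarity, rf_proximity, scree_select)
from .io import ROIMatrix
from .stats import (CharacterizationReport, characterize_clusters,
                    effect_size_map, transition_table)
from .trajectories import TrajectoryFit, fit_trajectory
from .validity import DEFAULT_INDICES, ClusterSolution, ensemble_vote, \
    filter_small_clusters


@dataclass
class SubtypeConfig:
    """Tunable parameters of one subtyping run."""

    mode: str = "unadjusted"          # "unadjusted" | "adjusted"
    n_trees: int = 2000
    min_samples_leaf: int | str = "auto"   # RF terminal-node size (n/12)
    n_components: int = 3             # MDS dimension (scree override)
    k_min: int = 2
    k_max: int = 15
    min_cluster_size: int = 10
    indices: tuple = DEFAULT_INDICES
    dissimilarity: str = "sqrt"       # "sqrt" -> sqrt(1-p), "linear" -> 1-p
    cluster_on_embedding: bool = True
    reference_cohort: str | None = None
    k_override: int | None = None     # force a cut at this k instead of the vote

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class AtrophySubtypeModel:
    """Subtyping model over a pooled multi-cohort PD/HC morphometry sample.

    Parameters
    ----------
    table : subject covariate table (one row per subject, validated).
    matrix : 41-feature hemisphere-averaged :class:`ROIMatrix`, rows aligned
        with ``table``.
    mode : "unadjusted" keeps the global-atrophy (severity) dimension in the
        clustering input; "adjusted" removes it with the per-subject
        severity normalization, so clustering sees atrophy *patterns* only.
    **config : any :class:`SubtypeConfig` field.

    Examples
    --------
    >>> from pdsubtypes import simulate
    >>> t, m, _ = simulate.generate_dataset(simulate.default_cohorts(0.2),
    ...                                     simulate.severity_subtypes(), seed=0)
    >>> res = AtrophySubtypeModel(t, m, n_trees=300).fit(seed=0)
    >>> res.solution.retained >= 2
    True
    """

    def __init__(self, table: pd.DataFrame, matrix: ROIMatrix,
                 mode: str = "unadjusted", **config):
        if list(table["subject_id"].astype(str)) != list(matrix.subjects):
            raise ValueError("subject table and ROI matrix are not aligned")
        if mode not in ("unadjusted", "adjusted"):
            raise ValueError("mode must be 'unadjusted' or 'adjusted'")
        self.table = table.reset_index(drop=True)
        self.matrix = matrix
        self.config = SubtypeConfig(mode=mode, **config)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_csv(cls, subjects_path, roi_path, **config) -> "AtrophySubtypeModel":
        """Build from a subject table CSV and a hemisphere-averaged ROI CSV."""
        from .io import read_subject_table
        table, report = read_subject_table(subjects_path)
        if report.n_dropped:
            warnings.warn(f"dropped {report.n_dropped} invalid subject rows")
        roi = pd.read_csv(roi_path, index_col=0)
        roi.index = roi.index.astype(str)
        roi = roi.loc[table["subject_id"].astype(str)]
        matrix = ROIMatrix.from_frame(roi)
        return cls(table, matrix, **config)

    @classmethod
    def from_generator(cls, cohorts, subtypes, seed: int, *,
                       generator_kwargs=None, **config):
        """Build from the synthetic multi-cohort generator."""
        from .simulate import generate_dataset
        table, matrix, truth = generate_dataset(cohorts, subtypes, seed,
                                                **(generator_kwargs or {}))
        model = cls(table, matrix, **config)
        model.truth = truth
        return model

    # -- fitting ---------------------------------------------------------
    @property
    def pd_mask(self) -> np.ndarray:
        return (self.table["group"] == "PD").to_numpy()

    @property
    def hc_mask(self) -> np.ndarray:
        return (self.table["group"] == "HC").to_numpy()

    def fit(self, seed: int = 0) -> "AtrophySubtypeResults":
        """Run the full pipeline; deterministic given ``seed``."""
        cfg = self.config
        base, chain = harmonize.build_clustering_input(
            self.matrix, self.table, mode="unadjusted",
            reference_cohort=cfg.reference_cohort)
        clustering_input = harmonize.severity_adjust(base) \
            if cfg.mode == "adjusted" else base

        pd_mask = self.pd_mask
        if pd_mask.sum() < 10:
            raise ValueError("need at least 10 PD subjects to cluster")
        X = clustering_input.values[pd_mask]
        # scale features so thickness (mm) and volume (mm^3) weigh equally
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

        prox = rf_proximity(Xs, n_trees=cfg.n_trees, seed=seed,
                            min_samples_leaf=cfg.min_samples_leaf)
        D = proximity_to_dissimilarity(prox, transform=cfg.dissimilarity)
        emb = classical_mds(D, d=cfg.n_components)
        points = emb.coordinates if cfg.cluster_on_embedding else Xs
        tree = average_linkage(points)
        vote = ensemble_vote(points, tree, range(cfg.k_min, cfg.k_max + 1),
                             cfg.indices)
        k = cfg.k_override or vote.winner
        labels = cut_tree(tree, k)
        solution = filter_small_clusters(
            labels, min_size=cfg.min_cluster_size,
            provenance={"mode": cfg.mode, "config": cfg.hash(), "seed": seed,
                        "k": int(k)})
        return AtrophySubtypeResults(
            model=self, seed=seed, harmonized=base, chain=chain,
            clustering_input=clustering_input, proximity=prox, embedding=emb,
            tree=tree, vote=vote, solution=solution)


class AtrophySubtypeResults:
    """Fitted subtyping results: labels, diagnostics and downstream analyses."""

    def __init__(self, model, seed, harmonized, chain, clustering_input,
                 proximity, embedding, tree, vote, solution: ClusterSolution):
        self.model = model
        self.seed = seed
        self.harmonized = harmonized          # field/eTIV/cohort-adjusted matrix
        self.chain = chain
        self.clustering_input = clustering_input
        self.proximity = proximity
        self.embedding = embedding
        self.tree = tree
        self.vote = vote
        self.solution = solution

    # -- label views -----------------------------------------------------
    @property
    def pd_subjects(self) -> list[str]:
        return self.model.table.loc[self.model.pd_mask, "subject_id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        """Cluster label per PD subject (0 = excluded small cluster)."""
        return self.solution.labels

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.pd_subjects,
                             "cluster": self.solution.labels})

    def scree_dimension(self, max_d: int = 10) -> int:
        """Data-driven MDS dimension from the eigenvalue scree (no override)."""
        return scree_select(self.embedding.eigenvalues, max_d=max_d)

    # -- downstream analyses --------------------------------------------
    def characterize(self, **kwargs) -> CharacterizationReport:
        """Cluster comparison on demographic/clinical variables (PD only)."""
        sub = self.model.table.loc[self.model.pd_mask].reset_index(drop=True)
        return characterize_clusters(sub, self.solution.labels, **kwargs)

    def effect_size_maps(self, covariates=("age", "field_strength", "cohort")):
        """Per-cluster ANCOVA+FDR Cohen's d atrophy maps versus HC.

        Maps are computed on the harmonization-chain output before severity
        normalization (thickness/volumes adjusted for field strength, eTIV
        and cohort).
        """
        tab = self.model.table
        maps = {}
        pd_idx = np.flatnonzero(self.model.pd_mask)
        for c in sorted(self.solution.cluster_sizes):
            cmask = np.zeros(len(tab), bool)
            cmask[pd_idx[self.solution.labels == c]] = True
            maps[c] = effect_size_map(self.harmonized, tab, cmask,
                                      self.model.hc_mask, covariates=covariates)
        return maps

    def transition(self, other: "AtrophySubtypeResults"):
        """Cross-tabulate this solution against another (e.g. other mode)."""
        return transition_table(self.solution.labels, other.solution.labels,
                                self.pd_subjects, other.pd_subjects)

    def fit_trajectories(self, visits: pd.DataFrame,
                         outcome: str = "updrs3", **kwargs) -> TrajectoryFit:
        """Linear mixed model of a longitudinal outcome across clusters."""
        base = self.model.table.loc[self.model.pd_mask].reset_index(drop=True)
        return fit_trajectory(visits, base, self.solution.labels, outcome,
                              **kwargs)

    def validate_per_cohort(self, min_pd: int = 30) -> dict:
        """Re-run the pipeline inside each cohort; report overlap vs pooled.

        Returns cohort -> {"winner": k, "ari": overlap with the pooled
        solution on that cohort's subjects}.  Cohorts with fewer than
        ``min_pd`` PD subjects (or no HC for the reference fits) are skipped.
        """
        out = {}
        tab = self.model.table
        for cohort in tab["cohort"].unique():
            sel = (tab["cohort"] == cohort).to_numpy()
            sub = tab.loc[sel].reset_index(drop=True)
            if (sub["group"] == "PD").sum() < min_pd or (sub["group"] == "HC").sum() < 3:
                continue
            m = ROIMatrix(self.model.matrix.values[sel],
                          sub["subject_id"].tolist(),
                          self.model.matrix.features, self.model.matrix.kinds)
            cfg = {k: v for k, v in asdict(self.model.config).items()}
            cfg["reference_cohort"] = None
            mode = cfg.pop("mode")
            local = AtrophySubtypeModel(sub, m, mode=mode, **cfg).fit(self.seed)
            _, _, _, _, ari = self.transition(local)
            out[str(cohort)] = {"winner": local.vote.winner, "ari": ari}
        return out

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        s = self.solution
        sizes = ", ".join(f"cl{c}={n}" for c, n in s.cluster_sizes.items())
        lines = [
            "Atrophy subtyping results",
            "=" * 25,
            f"mode: {self.model.config.mode}   seed: {self.seed}   "
            f"config: {self.model.config.hash()}",
            f"PD subjects clustered: {len(self.labels)}   "
            f"HC reference: {int(self.model.hc_mask.sum())}",
            f"adjustment chain: {' -> '.join(self.clustering_input.adjustments)}",
            f"ensemble vote: winner k={self.vote.winner}"
            + (f", runner-up k={self.vote.runner_up}" if self.vote.runner_up else ""),
            f"vote tally: {dict(sorted(self.vote.tally.items()))}",
            f"retained clusters ({s.retained}, min size "
            f"{self.model.config.min_cluster_size}): {sizes}",
        ]
        if s.excluded_sizes:
            lines.append(f"excluded cluster sizes: {s.excluded_sizes}")
        ev = self.embedding.eigenvalues
        pos = ev[ev > 0]
        lines.append(f"MDS: {self.embedding.d} components, top eigenvalue "
                     f"share {pos[:self.embedding.d].sum() / pos.sum():.2f}")
        return "\n".join(lines)

    # -- plots -----------------------------------------------------------
    def plot_scree(self, ax=None, max_d: int = 10):
        """Eigenvalue scree of the MDS decomposition."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ev = self.embedding.eigenvalues[:max_d]
        ax.plot(np.arange(1, len(ev) + 1), ev, "o-")
        ax.set_xlabel("component")
        ax.set_ylabel("eigenvalue")
        ax.axvline(self.embedding.d, ls="--", color="gray")
        return ax

    def plot_embedding(self, ax=None, components=(0, 1)):
        """Scatter of two MDS components colored by cluster."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        xy = self.embedding.coordinates[:, list(components)]
        for c in sorted(np.unique(self.labels)):
            sel = self.labels == c
            name = f"cl{c}" if c else "excluded"
            ax.scatter(xy[sel, 0], xy[sel, 1], s=12, label=name)
        ax.set_xlabel(f"MDS {components[0] + 1}")
        ax.set_ylabel(f"MDS {components[1] + 1}")
        ax.legend()
        return ax

    # -- persistence -----------------------------------------------------
    def save(self, outdir) -> Path:
        """Persist run artifacts under ``outdir/run-<hash>-seed<seed>/``.

        Refuses to overwrite an existing run directory.
        """
        cfg = self.model.config
        run = Path(outdir) / f"run-{cfg.hash()}-seed{self.seed}"
        if run.exists():
            raise FileExistsError(f"run directory exists: {run}")
        run.mkdir(parents=True)
        self.labels_frame().to_csv(run / "labels.csv", index=False)
        pd.DataFrame(self.proximity.values, index=self.pd_subjects,
                     columns=self.pd_subjects).to_csv(run / "proximity.csv")
        pd.DataFrame(self.embedding.coordinates, index=self.pd_subjects,
                     columns=[f"mds{i+1}" for i in range(self.embedding.d)]
                     ).to_csv(run / "embedding.csv")
        np.savetxt(run / "linkage.csv", self.tree.merges, delimiter=",",
                   header="left,right,height,size", comments="")
        (run / "vote.json").write_text(json.dumps(self.vote.to_dict(), indent=1))
        harmonize.chain_to_json(self.chain, run / "adjustments.json")
        meta = {"config": asdict(cfg), "config_hash": cfg.hash(),
                "seed": self.seed,
                "cluster_sizes": self.solution.cluster_sizes,
                "excluded_sizes": self.solution.excluded_sizes}
        (run / "run.json").write_text(json.dumps(meta, indent=1, default=str))
        return run
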