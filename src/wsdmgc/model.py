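"""The WS-DMGC model: weakly supervised deep-metric graph clustering.

Organised like a statsmodels estimator: :class:`WSDMGC` is constructed
from a :class:`~wsdmgc.datasets.SampleSet` plus a
:class:`~wsdmgc.config.RunConfig`; :meth:`WSDMGC.fit` runs the iterative
pipeline and returns a :class:`WSDMGCResults` carrying the final labels,
the trained embedder, the iteration history and evaluation metrics.

Each outer iteration: (1) (re)train the metric-embedding network on the
current labeled set S_l — warm-started with a reduced epoch count after
the first pass; (2) embed all samples; (3) classify the unlabeled ones
(weak labels L1); (4) constrained spectral clustering over all samples
(cluster labels L2); (5) align cluster ids to class ids on the labeled
samples; (6) promote the unlabeled samples whose L1 and aligned L2 agree
(strong labels); (7) promote the S nearest-to-centroid unlabeled members
of each cluster. The loop ends when S_u is empty or the iteration cap is
reached; a two-stage confidence fallback guarantees termination when the
agreement rule alone stalls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedder as emb_mod
from . import graph as graph_mod
from .config import RunConfig
from .datasets import DataValidationError, SampleSet
from .metrics import MetricsReport, evaluate_labels, silhouette
from .propagation import (PropagationState, SOURCE_FALLBACK,
                          align_clusters_to_classes, agreement_update,
                          confidence_fallback, knn_label_update)

logger = logging.getLogger("wsdmgc")


class WSDMGC:
    """Weakly supervised deep-metric graph clustering model.

    Parameters
    ----------
    dataset
        Samples with at least one labeled member per class. Hidden true
        labels on unlabeled samples, if present, are used only for
        evaluation.
    config
        Hyperparameters; keyword overrides are applied on top.
    """

    def __init__(self, dataset: SampleSet, config: RunConfig | None = None,
                 **overrides):
        config = (config or RunConfig()).replace(**overrides) if overrides \
            else (config or RunConfig())
        self.dataset = dataset
        self.config = config
        self.n_classes = dataset.n_classes
        if self.n_classes < 2:
            raise DataValidationError("dataset must contain >= 2 classes")
        init_labels = dataset.y[dataset.labeled]
        present = np.unique(init_labels)
        if len(present) < self.n_classes:
            raise DataValidationError(
                "every class needs at least one labeled sample; missing: "
                f"{sorted(set(range(self.n_classes)) - set(present))}")
        self.k = config.n_clusters or self.n_classes

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, feature_columns=None,
                       label_column: str = "label",
                       labeled_column: str = "labeled",
                       config: RunConfig | None = None, **overrides) -> "WSDMGC":
        """Build from a tidy frame of features + label/labeled columns."""
        feats = feature_columns or [c for c in frame.columns
                                    if c not in (label_column, labeled_column,
                                                 "sample_id")]
        ids = frame["sample_id"].astype(str).to_numpy(dtype=object) \
            if "sample_id" in frame else \
            np.array([str(i) for i in range(len(frame))], dtype=object)
        ds = SampleSet(ids=ids,
                       X=frame[feats].to_numpy(dtype=np.float64),
                       y=frame[label_column].fillna(-1).to_numpy(dtype=np.int64),
                       labeled=frame[labeled_column].astype(bool).to_numpy())
        return cls(ds, config=config, **overrides)

    # ------------------------------------------------------------------
    def fit(self) -> "WSDMGCResults":
        cfg = self.config
        ds = self.dataset
        state = PropagationState.from_dataset(ds, self.n_classes)
        params = None
        converged = True
        stalled = 0
        fallback_rounds = 0

        if len(state.S_u) == 0:
            logger.info("dataset fully labeled; nothing to propagate")
            return self._results(state, None, None, converged=True)

        if not cfg.propagation:
            return self._fit_no_propagation(state)

        while state.iteration < cfg.max_total_iters and len(state.S_u) > 0:
            state.iteration += 1
            epochs = cfg.epochs if params is None else cfg.warm_epochs
            params, hist = emb_mod.fit_embedder(
                (ds.X[state.labeled_mask],
                 state.working[state.labeled_mask]),
                cfg, init=params, epochs=epochs, n_classes=self.n_classes)
            F = emb_mod.embed(ds, params)
            state.L1, state.confidence = emb_mod.classify(ds, params)
            self._cluster_stage(state, F, cfg.seed + 1009 * state.iteration)
            agreed = agreement_update(state)
            promoted = knn_label_update(state, F, cfg.knn_S)
            n_fallback = 0
            if len(agreed) + len(promoted) == 0:
                stalled += 1
                if stalled >= cfg.max_stall_iters:
                    fallback_rounds += 1
                    n_fallback = len(confidence_fallback(state))
                    if fallback_rounds > 3 or n_fallback == 0:
                        # terminal fallback: trust the classifier for the rest
                        rest = state.S_u
                        state.promote(rest, state.L1[rest], SOURCE_FALLBACK)
                        n_fallback += len(rest)
                        converged = False
                        logger.warning(
                            "agreement rule never fired for %d samples; "
                            "assigned classifier labels", len(rest))
            else:
                stalled = 0
            state.record(n_agreement=len(agreed), n_knn=len(promoted),
                         n_fallback=n_fallback,
                         train_loss=float(hist["loss"].iloc[-1]))

        surviving = state.S_u
        if len(surviving) > 0:
            converged = False
            logger.warning("iteration cap reached with %d unlabeled samples; "
                           "assigned classifier labels: %s", len(surviving),
                           list(ds.ids[surviving]))
            state.promote(surviving, state.L1[surviving], SOURCE_FALLBACK)
            state.record(n_agreement=0, n_knn=0, n_fallback=len(surviving),
                         train_loss=np.nan)
        F = emb_mod.embed(ds, params) if params is not None else None
        return self._results(state, params, F, converged=converged)

    def _cluster_stage(self, state: PropagationState, F: np.ndarray,
                       seed: int) -> None:
        """Constrained spectral clustering with labeled-agreement bandwidth
        selection.

        With ``sigma="auto"`` several candidate bandwidths (multiples of
        the within-class labeled median) are tried and the partition that
        agrees best with the known labels of S_l is kept — the labeled
        samples act as a validation set for the kernel scale. A fixed
        numeric ``sigma`` skips the search.
        """
        cfg = self.config
        if cfg.sigma == "auto" and self.k == self.n_classes:
            base = graph_mod.within_class_sigma(F, state.working, scale=1.0)
            candidates = [base * s for s in (1.5, 2.0, 2.5, 3.0)]
        else:
            candidates = [cfg.sigma if cfg.sigma != "auto"
                          else graph_mod.within_class_sigma(F, state.working)]
        labeled = state.labeled_mask
        best_score = -np.inf
        for sigma in candidates:
            graph = graph_mod.graph_laplacian(graph_mod.build_similarity(
                F, labels=state.working, sigma=sigma))
            L2 = graph_mod.spectral_partition(graph, self.k, seed=seed,
                                              order=cfg.eigvec_order)
            if self.k == self.n_classes:
                alignment = align_clusters_to_classes(L2, state.working,
                                                      self.n_classes)
                aligned = np.array([alignment[int(c)] for c in L2])
                score = float(np.mean(aligned[labeled] ==
                                      state.working[labeled]))
            else:
                alignment, score = None, 0.0
            if score > best_score:
                best_score = score
                state.L2, state.alignment = L2, alignment

    def _fit_no_propagation(self, state: PropagationState) -> "WSDMGCResults":
        """Ablation variant: train once, cluster once, no label promotion."""
        cfg = self.config
        ds = self.dataset
        state.iteration = 1
        params, hist = emb_mod.fit_embedder(
            (ds.X[state.labeled_mask], state.working[state.labeled_mask]),
            cfg, n_classes=self.n_classes)
        F = emb_mod.embed(ds, params)
        state.L1, state.confidence = emb_mod.classify(ds, params)
        self._cluster_stage(state, F, cfg.seed)
        aligned = state.aligned_L2()
        rest = state.S_u
        state.promote(rest, aligned[rest], "cluster")
        state.record(n_agreement=0, n_knn=0, n_fallback=0,
                     train_loss=float(hist["loss"].iloc[-1]))
        return self._results(state, params, F, converged=True)

    def _results(self, state, params, F, converged) -> "WSDMGCResults":
        return WSDMGCResults(model=self, state=state, params=params,
                             embeddings=F, converged=converged)


@dataclass
class WSDMGCResults:
    """Fit results: final labels, trained embedder, history, diagnostics."""

    model: WSDMGC
    state: PropagationState
    params: emb_mod.EmbedderParams | None
    embeddings: np.ndarray | None
    converged: bool

    # -- primary outputs ----------------------------------------------------
    @property
    def labels_(self) -> np.ndarray:
        return self.state.working.copy()

    @property
    def sources_(self) -> np.ndarray:
        return self.state.source.copy()

    @property
    def n_iterations(self) -> int:
        return self.state.iteration

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    def to_frame(self) -> pd.DataFrame:
        ds = self.model.dataset
        return pd.DataFrame({
            "sample_id": ds.ids,
            "predicted_label": self.labels_,
            "source": self.sources_,
            "iteration": self.state.promoted_at,
        })

    # -- evaluation ---------------------------------------------------------
    def metrics(self) -> MetricsReport:
        """Score the final labels against hidden ground truth.

        Requires every sample to carry a true label (phantoms and masked
        datasets do); silhouette is computed on the final embeddings.
        """
        ds = self.model.dataset
        if np.any(ds.y < 0):
            raise DataValidationError(
                "ground-truth labels unavailable for some samples")
        points = self.embeddings if self.embeddings is not None else ds.features
        return evaluate_labels(self.labels_, ds.y, points=points)

    def mean_silhouette(self) -> float:
        points = self.embeddings if self.embeddings is not None \
            else self.model.dataset.features
        _, sc = silhouette(points, self.labels_)
        return sc

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        ds = self.model.dataset
        cfg = self.model.config
        lines = [
            "WS-DMGC results",
            "=" * 46,
            f"{'samples':<28}{len(ds):>18}",
            f"{'classes / clusters':<28}{self.model.n_classes:>9}{self.model.k:>9}",
            f"{'initially labeled':<28}{int((self.state.promoted_at == 0).sum()):>18}",
            f"{'outer iterations':<28}{self.n_iterations:>18}",
            f"{'converged':<28}{str(self.converged):>18}",
            f"{'lambda1 / lambda2':<28}{cfg.lambda1:>9.3g}{cfg.lambda2:>9.3g}",
            f"{'triplet margin alpha':<28}{cfg.alpha_margin:>18.3g}",
            f"{'seed':<28}{cfg.seed:>18}",
        ]
        src = pd.Series(self.sources_).value_counts()
        lines.append("-" * 46)
        for name, count in src.items():
            lines.append(f"{'labels from ' + str(name):<28}{count:>18}")
        if np.all(ds.y >= 0):
            rep = self.metrics()
            lines.append("-" * 46)
            lines.append(f"{'purity':<28}{rep.purity:>18.4f}")
            lines.append(f"{'best-map accuracy':<28}{rep.acc:>18.4f}")
            lines.append(f"{'NMI':<28}{rep.nmi:>18.4f}")
            if rep.mean_silhouette is not None:
                lines.append(f"{'mean silhouette':<28}{rep.mean_silhouette:>18.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write ``labels.csv`` and ``report.json`` under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "labels.csv", index=False)
        report = {
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "config": self.model.config.to_dict(),
            "history": self.state.history,
        }
        if np.all(self.model.dataset.y >= 0):
            report["metrics"] = self.metrics().to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2))

    def plot_history(self, ax=None):
        """Labeled-set growth per outer iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["iteration"], h["n_labeled"], marker="o", label="|S_l|")
        ax.plot(h["iteration"], h["n_unlabeled"], marker="s", label="|S_u|")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel("samples")
        ax.legend()
        return ax


def run_wsdmgc(dataset: SampleSet, config: RunConfig | None = None,
               **overrides) -> WSDMGCResults:
    """One-call convenience wrapper: ``WSDMGC(dataset, config).fit()``."""
    return WSDMGC(dataset, config=config, **overrides).fit()
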