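"""Run configuration: hyperparameters of the embedder, graph stage and propagation loop.

Defaults follow the stable operating region reported for the method
(``lambda1`` in [0.5, 0.7], ``lambda2`` in [0.03, 0.05], three neighbours
promoted per cluster per round) and otherwise standard metric-learning
practice.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

logger = logging.getLogger("wsdmgc")


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraint."""


@dataclass
class RunConfig:
    """All tunable parameters of a WS-DMGC run.

    Parameters
    ----------
    lambda1
        Weight of the cross-entropy classification loss in the total
        objective ``L = L_M + lambda1 * L_C + lambda2 * ||W||_F^2``.
    lambda2
        Weight of the squared Frobenius norm of the network weights
        (weight decay) in the total objective.
    alpha_margin
        Triplet margin: anchor-negative squared distance must exceed
        anchor-positive squared distance by at least this much.
    contrastive_margin
        Margin ``m`` of the contrastive (Siamese) loss used by the
        ablation variants.
    sigma
        Gaussian kernel bandwidth of the similarity graph; ``"auto"``
        calibrates it on the within-class labeled distances, validated
        against the labeled samples (see the graph module).
    n_clusters
        Number of spectral clusters ``k``; ``None`` means "use the number
        of classes of the dataset" (the method assumes one cluster per
        subtype).
    knn_S
        Number of unlabeled samples promoted per cluster per round by the
        nearest-to-centroid label update (``S``).
    embed_dim
        Dimension ``d`` of the metric embedding space.
    conv_channels
        Channel widths of the convolutional blocks used for image inputs.
    hidden_dims
        Sizes of the fully connected hidden layers of the embedding trunk.
    samples_per_class, extra_negatives
        Mini-batch plan for online triplet mining: every class contributes
        up to ``samples_per_class`` samples, plus ``extra_negatives``
        additional random samples.
    restarts
        Independent cold-start training runs; the one with the best
        training loss is kept (batch-hard training has high run-to-run
        variance).
    epochs, warm_epochs
        Training epochs for the initial fit and for the warm-started
        refits on later outer iterations.
    learning_rate, momentum
        SGD parameters.
    hinge
        If True (default) the triplet loss is hinged at zero; False gives
        the literal unhinged sum.
    loss
        ``"triplet"`` or ``"contrastive"`` — the metric-learning objective.
    propagation
        If False, skip the label-propagation loop (train once, cluster
        once): the "no propagation" ablation variants.
    eigvec_order
        ``"smallest"`` (standard) or ``"largest"`` (literal reading of the
        top-k eigenvector step) for the spectral embedding.
    max_stall_iters, max_total_iters
        Stall and hard iteration limits of the outer loop.
    seed
        Single integer seed from which all randomness flows.
    """

    lambda1: float = 0.6
    lambda2: float = 0.04
    alpha_margin: float = 1.0
    contrastive_margin: float = 1.0
    sigma: Union[float, str] = "auto"
    n_clusters: int | None = None
    knn_S: int = 3
    embed_dim: int = 64
    conv_channels: tuple[int, ...] = (8, 16, 32)
    hidden_dims: tuple[int, ...] = (256,)
    samples_per_class: int = 4
    extra_negatives: int = 8
    restarts: int = 2
    epochs: int = 160
    warm_epochs: int = 6
    learning_rate: float = 0.008
    momentum: float = 0.9
    hinge: bool = True
    loss: str = "triplet"
    propagation: bool = True
    eigvec_order: str = "smallest"
    max_stall_iters: int = 3
    max_total_iters: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def require(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        require(self.lambda1 >= 0, "lambda1 must be >= 0")
        require(self.lambda2 >= 0, "lambda2 must be >= 0")
        require(self.alpha_margin > 0, "alpha_margin must be > 0")
        require(self.contrastive_margin > 0, "contrastive_margin must be > 0")
        if isinstance(self.sigma, str):
            require(self.sigma == "auto", 'sigma must be a positive number or "auto"')
        else:
            require(self.sigma > 0, "sigma must be > 0")
        if self.n_clusters is not None:
            require(self.n_clusters >= 1, "n_clusters must be >= 1")
        require(self.knn_S >= 1, "knn_S must be >= 1")
        require(self.embed_dim >= 1, "embed_dim must be >= 1")
        require(self.samples_per_class >= 2, "samples_per_class must be >= 2")
        require(self.extra_negatives >= 0, "extra_negatives must be >= 0")
        require(self.restarts >= 1, "restarts must be >= 1")
        require(self.epochs >= 1, "epochs must be >= 1")
        require(self.warm_epochs >= 1, "warm_epochs must be >= 1")
        require(self.learning_rate > 0, "learning_rate must be > 0")
        require(0 <= self.momentum < 1, "momentum must be in [0, 1)")
        require(self.loss in ("triplet", "contrastive"),
                'loss must be "triplet" or "contrastive"')
        require(self.eigvec_order in ("smallest", "largest"),
                'eigvec_order must be "smallest" or "largest"')
        require(self.max_stall_iters >= 1, "max_stall_iters must be >= 1")
        require(self.max_total_iters >= 1, "max_total_iters must be >= 1")
        require(int(self.seed) == self.seed and self.seed >= 0,
                "seed must be a non-negative integer")

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        d["conv_channels"] = list(self.conv_channels)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config file.

    Missing keys take the documented defaults; unknown keys are rejected.
    The resolved configuration is echoed to the package logger.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = sorted(set(raw) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("hidden_dims", "conv_channels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg
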