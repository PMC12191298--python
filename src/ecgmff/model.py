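"""Model/Results interface over the fused multi-domain classifier.

`MffClassifier` is built from data (a :class:`~ecgmff.train_eval.BeatDataset`
or raw :class:`~ecgmff.records.EcgRecord` lists), holds the architecture and
protocol configuration, and ``fit()`` returns an :class:`MffResults` carrying
the trained network, the loss trace, the held-out metrics and a ``summary()``
table — the same shape statsmodels gives its estimators.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import ImagingConfig
from .nn import MffNet
from .records import EcgRecord
from .train_eval import (
    BeatDataset,
    MetricsReport,
    Split,
    SplitSpec,
    TrainConfig,
    evaluate,
    train,
)


class MffClassifier:
    """Multi-domain feature-fusion ECG classifier.

    Parameters
    ----------
    dataset : BeatDataset
        Aligned beat / GAF-image / ST-image features with labels and
        patient ids.
    branches : tuple of str
        Subset of ``("beat", "gaf", "st")``; fewer branches shrink the
        fusion head (used for ablation).
    width_multiplier : float
        Scales the four stage widths (64/128/256/512); 1.0 is the full
        network, 0.125 the desk-scale variant.
    task : str
        "detection" (MI vs healthy) or "localization" (MI subtype).
    seed : int
        Controls weight initialization and dropout.
    """

    def __init__(
        self,
        dataset: BeatDataset,
        branches: tuple[str, ...] = ("beat", "gaf", "st"),
        width_multiplier: float = 1.0,
        task: str = "localization",
        seed: int = 0,
    ):
        if task not in ("detection", "localization"):
            raise ValueError("task must be detection or localization")
        if task == "detection" and len(dataset.classes) != 2:
            raise ValueError(
                "detection requires exactly 2 classes; got "
                f"{dataset.classes}"
            )
        self.dataset = dataset
        self.branches = tuple(branches)
        self.width_multiplier = width_multiplier
        self.task = task
        self.seed = seed

    @classmethod
    def from_records(
        cls,
        records: list[EcgRecord],
        imaging_config: ImagingConfig | None = None,
        **kwargs,
    ) -> "MffClassifier":
        """Preprocess, segment and image raw records, then build the model."""
        dataset = BeatDataset.from_records(records, imaging_config)
        return cls(dataset, **kwargs)

    def build_network(self) -> MffNet:
        return MffNet(
            n_classes=len(self.dataset.classes),
            branches=self.branches,
            width_multiplier=self.width_multiplier,
            beat_channels=self.dataset.beats.shape[1],
            image_channels=self.dataset.gafs.shape[1],
            seed=self.seed,
        )

    def fit(
        self,
        split: Split | SplitSpec | None = None,
        train_config: TrainConfig | None = None,
    ) -> "MffResults":
        """Train on the split's training partition and score the test one.

        ``split`` may be a concrete :class:`Split`, a :class:`SplitSpec`
        (materialized here), or None for an inter-patient 7:3 default.
        """
        from .train_eval import make_split

        if split is None:
            split = SplitSpec(seed=self.seed)
        if isinstance(split, SplitSpec):
            split = make_split(self.dataset, split)
        train_config = train_config or TrainConfig(seed=self.seed)
        network = self.build_network()
        loss_trace = train(network, self.dataset, split.train_idx, train_config)
        test_report = evaluate(
            network, self.dataset, split.test_idx, task=self.task
        )
        return MffResults(
            model=self,
            network=network,
            split=split,
            train_config=train_config,
            loss_trace=loss_trace,
            test_report=test_report,
        )


@dataclass
class MffResults:
    """Fitted-model container: network, protocol, loss trace and metrics."""

    model: MffClassifier
    network: MffNet
    split: Split
    train_config: TrainConfig
    loss_trace: list[float]
    test_report: MetricsReport
    _extra: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        """Overall test accuracy AccT in percent."""
        return self.test_report.acc_total

    def predict(self, dataset: BeatDataset | None = None) -> np.ndarray:
        dataset = dataset or self.model.dataset
        return self.network.predict(
            dataset.inputs(branches=self.model.branches)
        )

    def summary(self) -> str:
        m = self.model
        head = [
            "Multi-domain feature-fusion ECG classifier",
            "=" * 46,
            f"task:              {m.task}",
            f"classes:           {', '.join(m.dataset.classes)}",
            f"branches:          {', '.join(m.branches)}",
            f"width multiplier:  {m.width_multiplier:g}",
            f"parameters:        {self.network.n_parameters:,}",
            f"train / test:      {self.split.train_idx.size} / "
            f"{self.split.test_idx.size} beats",
            f"epochs:            {self.train_config.epochs} "
            f"(final loss {self.loss_trace[-1]:.4f})",
            "",
        ]
        return "\n".join(head) + self.test_report.summary()

    def plot_loss(self, ax=None):
        """Loss-trace plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_trace) + 1), self.loss_trace)
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean cross-entropy loss")
        return ax
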