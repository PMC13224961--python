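"""Model/Results front end.

:class:`CodonAdapter` bundles a dataset, a frozen backbone and an adapter
architecture, in the style of statistical modelling packages: construct the
model from data, call :meth:`~CodonAdapter.fit`, and work with the returned
:class:`AdapterResults` — predictions, per-split rank correlations, training
history and a text summary. The functional layer underneath
(:mod:`codonmoe.train`, :mod:`codonmoe.adapters`) remains available for
scripted experiments.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .adapters import save_checkpoint
from .backbone import BackboneContract, SyntheticBackbone, embed_dataset
from .baselines import ParamBudget, build_dense_baseline, count_params
from .errors import ValidationError
from .moe import MoEConfig
from .pro import ProHeadConfig
from .sequence_io import Dataset, SequenceRecord
from .train import (DatasetSplit, EvalReport, FitResult, TrainConfig,
                    evaluate, split, train)
from .adapters import make_adapter

__all__ = ["CodonAdapter", "AdapterResults"]


class CodonAdapter:
    """A codon-aware adapter model over a frozen backbone.

    Parameters
    ----------
    data : Dataset
        Sequences with scalar targets; all sequences must share one length.
    adapter : {"mean", "base", "pro", "dense"}
        Architecture variant. ``dense`` builds the parameter-matched MLP
        control (budget = the pro adapter's count) unless ``dense_hidden``
        is given.
    backbone : BackboneContract, optional
        Defaults to a :class:`SyntheticBackbone` with ``backbone_dim`` /
        ``backbone_seed``.
    frame_offset : {0, 1, 2}
        Reading frame; 0 assumes in-frame coding sequence from the first
        base.
    """

    def __init__(self, data: Dataset, adapter: str = "base",
                 backbone: BackboneContract | None = None,
                 frame_offset: int = 0,
                 moe_config: MoEConfig | None = None,
                 pro_config: ProHeadConfig | None = None,
                 dense_hidden: int | None = None,
                 backbone_dim: int = 16, backbone_seed: int = 7):
        if not data.has_targets:
            raise ValidationError("model construction requires a dataset with targets")
        self.data = data
        self.backbone = backbone or SyntheticBackbone(backbone_dim, backbone_seed)
        L, D = data.sequence_length(), self.backbone.embed_dim
        self.kind = adapter
        if adapter == "dense" and dense_hidden is None:
            ref = make_adapter("pro", L, D, frame_offset, moe_config, pro_config)
            target = count_params(ref.init_params(np.random.default_rng(0)))
            self.adapter = build_dense_baseline(L, D, ParamBudget(target))
        else:
            self.adapter = make_adapter(adapter, L, D, frame_offset,
                                        moe_config, pro_config, dense_hidden)
        self._embeddings = embed_dataset(self.backbone, data.sequences)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CodonAdapter":
        """Build from a DataFrame with columns id, sequence, target."""
        from .sequence_io import normalize_sequence
        records = [
            SequenceRecord(str(r.id), normalize_sequence(str(r.sequence),
                                                         record_id=str(r.id)),
                           float(r.target))
            for r in df.itertuples(index=False)
        ]
        return cls(Dataset(records, name="dataframe"), **kwargs)

    def fit(self, config: TrainConfig | None = None, *,
            dsplit: DatasetSplit | None = None, **config_overrides) -> "AdapterResults":
        cfg = config or TrainConfig(**config_overrides)
        if config is not None and config_overrides:
            cfg = replace(config, **config_overrides)
        if dsplit is None:
            dsplit = split(len(self.data), seed=cfg.seed)
        result = train(self.adapter, self.data, self.backbone, dsplit, cfg,
                       self._embeddings)
        report = evaluate(result, self.data, dsplit, self.backbone, self._embeddings)
        return AdapterResults(self, result, report, dsplit)


class AdapterResults:
    """Fitted adapter: estimates, diagnostics and prediction."""

    def __init__(self, model: CodonAdapter, fit_result: FitResult,
                 report: EvalReport, dsplit: DatasetSplit):
        self.model = model
        self.fit_result = fit_result
        self.report = report
        self.split = dsplit
        self.params = fit_result.params

    @property
    def spearman(self) -> dict[str, float]:
        """Rank correlation per split ({'train','val','test'})."""
        return dict(self.report.rho)

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.fit_result.history)

    @property
    def n_params(self) -> int:
        return count_params(self.params)

    def predict(self, data: Dataset | None = None) -> np.ndarray:
        """Predictions (original target scale); defaults to the fitted dataset."""
        if data is None:
            E = self.model._embeddings
        else:
            E = embed_dataset(self.model.backbone, data.sequences)
        return self.fit_result.predict(E)

    def save(self, path) -> None:
        save_checkpoint(path, self.model.adapter, self.params)

    def summary(self) -> str:
        """Plain-text fit summary."""
        lines = [
            "Codon adapter regression results",
            "=" * 44,
            f"{'Adapter:':<22}{self.model.kind}",
            f"{'Backbone dim D:':<22}{self.model.backbone.embed_dim}",
            f"{'Sequence length L:':<22}{self.model.adapter.L}",
            f"{'Trainable params:':<22}{self.n_params}",
            f"{'Epochs run:':<22}{len(self.fit_result.history)}",
            f"{'Seed:':<22}{self.fit_result.seed}",
            "-" * 44,
            f"{'split':<8}{'n':>6}{'Spearman rho':>16}",
        ]
        for s in ("train", "val", "test"):
            lines.append(f"{s:<8}{self.report.n[s]:>6}{self.report.rho[s]:>16.4f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self) -> str:
        rho = ", ".join(f"{k}={v:.3f}" for k, v in self.report.rho.items())
        return f"<AdapterResults {self.model.kind}: {rho}>"
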