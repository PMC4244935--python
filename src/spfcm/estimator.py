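"""Model/Results front end for the SP-FCM sweep.

``SPFCM`` holds the data and hyper-parameters; ``fit()`` runs the sweep
and returns an ``SPFCMResults`` carrying the selected partition, the full
per-C trace as a DataFrame, and a text ``summary()``.
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from .fcm import DataMatrix, FcmConfig
from .io import RunManifest, make_manifest, write_result
from .pipeline import SpfcmConfig, SpfcmResult, run_spfcm
from .pso import PsoConfig
from .shadowed import ReductionPolicy

__all__ = ["SPFCM", "SPFCMResults"]


class SPFCM:
    """Shadowed-set + particle-swarm fuzzy c-means with automatic C selection.

    Parameters
    ----------
    data:
        DataMatrix, ndarray or DataFrame of shape (N objects, P features).
    c_min, c_max:
        Cluster-count range to sweep; ``c_max`` should overestimate the
        expected count (rule of thumb: C <= sqrt(N)).
    epsilon:
        Cardinality threshold below which a cluster becomes a removal
        candidate.
    rho:
        Attrition rate in (0, 1): at most floor(rho * C) clusters are
        removed per reduction step (floored at one).
    m, tol, max_iter:
        FCM fuzzifier, prototype-stabilization tolerance, iteration cap.
    w, c1, c2, swarm_size, pso_iters:
        Particle-swarm inertia, acceleration coefficients, swarm size L
        and iteration count T.
    """

    def __init__(
        self,
        data,
        *,
        c_min: int = 2,
        c_max: int | None = None,
        epsilon: int = 10,
        rho: float = 0.1,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 100,
        w: float = 0.72,
        c1: float = 1.49,
        c2: float = 1.49,
        swarm_size: int = 20,
        pso_iters: int = 50,
    ):
        if isinstance(data, DataMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = DataMatrix(
                data.to_numpy(dtype=float),
                row_ids=[str(i) for i in data.index],
                feature_names=[str(c) for c in data.columns],
            )
        else:
            self.data = DataMatrix(np.asarray(data, dtype=float))
        if c_max is None:
            c_max = max(int(np.sqrt(self.data.n_objects)), c_min + 1)
        self.c_min = c_min
        self.c_max = c_max
        self.epsilon = epsilon
        self.rho = rho
        self.fcm_config = FcmConfig(m=m, tol=tol, max_iter=max_iter)
        self.pso_config = PsoConfig(w=w, c1=c1, c2=c2, L=swarm_size, T=pso_iters)
        self.policy = ReductionPolicy(epsilon=epsilon, rho=rho)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SPFCM":
        return cls(df, **kwargs)

    def _config(self, seed: int | None) -> SpfcmConfig:
        return SpfcmConfig(
            c_min=self.c_min,
            c_max=self.c_max,
            policy=self.policy,
            fcm=self.fcm_config,
            pso=self.pso_config,
            seed=seed,
        )

    def fit(self, seed: int | None = None) -> "SPFCMResults":
        started = datetime.datetime.now()
        cfg = self._config(seed)
        raw = run_spfcm(self.data, cfg)
        manifest = make_manifest(
            f"in-memory matrix {self.data.n_objects}x{self.data.n_features}",
            cfg,
            started,
        )
        return SPFCMResults(self, raw, manifest)


class SPFCMResults:
    """Fitted SP-FCM sweep: selected partition, validity trace, summary."""

    def __init__(self, model: SPFCM, raw: SpfcmResult, manifest: RunManifest):
        self.model = model
        self._raw = raw
        self.manifest = manifest
        self.selected_c = raw.best_C
        self.xb_ = raw.best_xb
        self.prototypes_ = raw.best_B.centers
        self.memberships_ = raw.best_U.u
        self.labels_ = raw.best_U.hard_labels()

    @property
    def raw(self) -> SpfcmResult:
        return self._raw

    @property
    def trace(self) -> pd.DataFrame:
        """Per-C validity panel of the sweep (one row per visited C)."""
        return pd.DataFrame(
            {
                "C": [r.C for r in self._raw.trace],
                "xb": [r.xb for r in self._raw.trace],
                "db": [r.db for r in self._raw.trace],
                "dunn": [r.dunn for r in self._raw.trace],
                "J": [r.J for r in self._raw.trace],
                "n_removed": [len(r.removed) for r in self._raw.trace],
            }
        )

    def summary(self) -> str:
        sizes = np.bincount(self.labels_, minlength=self.selected_c)
        lines = [
            "SP-FCM clustering results",
            "=" * 40,
            f"objects, features      {self.model.data.n_objects}, "
            f"{self.model.data.n_features}",
            f"C range swept          [{self.model.c_min}, {self.model.c_max}]",
            f"selected C             {self.selected_c}",
            f"Xie-Beni at selection  {self.xb_:.6g}",
            f"cluster sizes (hard)   {list(map(int, sizes))}",
            "",
            "validity trace (lower XB is better):",
            self.trace.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write memberships/prototypes/trace CSVs and the run manifest."""
        return write_result(
            self._raw,
            out_dir,
            row_ids=self.model.data.row_ids,
            manifest=self.manifest,
        )

    def plot_validity(self, ax=None):
        """XB-versus-C curve of the sweep (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.trace.sort_values("C")
        ax.plot(tr["C"], tr["xb"], marker="o")
        ax.axvline(self.selected_c, ls="--", color="grey")
        ax.set_xlabel("cluster count C")
        ax.set_ylabel("Xie-Beni index")
        return ax
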