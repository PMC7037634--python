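"""Scikit-learn style estimator computing the network Gibbs free energy.

`GibbsNetworkScorer` is a transformer over samples × genes matrices: ``fit``
binds an interaction network (and, for global rescaling, the matrix-wide
expression range) and ``transform`` maps each sample to its single network
Gibbs free energy value. It composes with sklearn pipelines and
``get_params`` / ``set_params`` / ``clone``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

import networkx as nx


class GibbsNetworkScorer(BaseEstimator, TransformerMixin):
    """Score expression samples by total network Gibbs free energy.

    Parameters
    ----------
    network:
        Undirected interaction graph over uppercased gene symbols. Required
        at ``fit`` time.
    rescale:
        If True (default), min–max rescale each sample's expression into
        [0, 1] before scoring; if False the input is taken as concentrations
        directly.
    rescale_scope:
        ``"sample"`` — min and max per sample (row); ``"global"`` — a single
        min and max over the whole matrix seen at ``fit``.
    rescale_over:
        ``"all"`` — range over every gene in the matrix (the transcriptome is
        rescaled first, then overlaid); ``"network"`` — range over
        network-overlapping genes only.

    Attributes
    ----------
    node_order_ : list of gene symbols, sorted — the deterministic summation
        order.
    adjacency_ : CSR adjacency matrix aligned with ``node_order_``.
    n_overlap_ : number of fitted feature genes present in the network.
    e_min_, e_max_ : global expression range (only for global scope).

    Notes
    -----
    Per sample, with concentrations c aligned to the node order and closed-
    neighborhood sums d = (A + I) c, the score is

        G = sum_i c_i ln(c_i / d_i)

    with the 0·ln(0) := 0 convention and ln(1) = 0 for isolated nodes. G is
    always ≤ 0 because c_i ≤ d_i.
    """

    def __init__(
        self,
        network: nx.Graph | None = None,
        rescale: bool = True,
        rescale_scope: str = "sample",
        rescale_over: str = "all",
    ) -> None:
        self.network = network
        self.rescale = rescale
        self.rescale_scope = rescale_scope
        self.rescale_over = rescale_over

    # -- sklearn API ---------------------------------------------------

    def fit(self, X=None, y=None):
        """Bind the network; with global rescaling, record the matrix range.

        ``X`` is a samples × genes DataFrame (or array whose columns are the
        sorted network nodes). May be omitted unless ``rescale_scope`` is
        ``"global"`` or overlap validation against a concrete matrix is
        wanted.
        """
        if self.network is None:
            raise ValueError("GibbsNetworkScorer requires a network")
        if self.rescale_scope not in {"sample", "global"}:
            raise ValueError(f"unknown rescale_scope {self.rescale_scope!r}")
        if self.rescale_over not in {"all", "network"}:
            raise ValueError(f"unknown rescale_over {self.rescale_over!r}")

        self.node_order_ = sorted(str(n) for n in self.network.nodes)
        if self.node_order_:
            adj = nx.to_scipy_sparse_array(
                self.network, nodelist=self.node_order_, format="csr", dtype=float
            )
            self.adjacency_ = adj + sp.identity(len(self.node_order_), format="csr")
        else:
            self.adjacency_ = sp.csr_matrix((0, 0))

        if X is not None:
            X = self._as_frame(X)
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            self.n_features_in_ = X.shape[1]
            self.n_overlap_ = int(X.columns.isin(self.node_order_).sum())
            if self.n_overlap_ == 0 and len(self.node_order_):
                raise ValueError("no overlap between expression genes and network nodes")
            if self.rescale and self.rescale_scope == "global":
                scope = self._range_frame(X)
                values = scope.to_numpy(dtype=float)
                self.e_min_ = float(np.nanmin(values))
                self.e_max_ = float(np.nanmax(values))
        elif self.rescale and self.rescale_scope == "global":
            raise ValueError("global rescale scope requires X at fit time")
        else:
            self.n_overlap_ = None
        return self

    def transform(self, X) -> np.ndarray:
        """Return an (n_samples, 1) array of total Gibbs free energies."""
        return self.score_samples(X).reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["total_gibbs_energy"], dtype=object)

    # -- scoring -------------------------------------------------------

    def score_samples(self, X) -> np.ndarray:
        """Total G per sample (1-D array, one value per row of ``X``)."""
        contrib, _ = self._contributions(X)
        return np.asarray(contrib.sum(axis=1))

    def per_node_table(self, X_row) -> pd.DataFrame:
        """Per-node breakdown (concentration, chemical potential,
        contribution) for a single-sample matrix."""
        frame = self._as_frame(X_row)
        if frame.shape[0] != 1:
            raise ValueError("per_node_table expects exactly one sample row")
        contrib, (c, mu) = self._contributions(frame)
        return pd.DataFrame(
            {
                "concentration": c[0],
                "chemical_potential": mu[0],
                "contribution": contrib[0],
            },
            index=pd.Index(self.node_order_, name="gene"),
        )

    # -- internals -----------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
            frame.columns = frame.columns.astype(str).str.strip().str.upper()
            return frame
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.node_order_):
            raise ValueError(
                "array input must have one column per sorted network node; "
                "pass a DataFrame with gene-symbol columns otherwise"
            )
        return pd.DataFrame(X, columns=self.node_order_)

    def _range_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.rescale_over == "network":
            cols = [c for c in frame.columns if c in set(self.node_order_)]
            return frame[cols]
        return frame

    def _concentrations(self, frame: pd.DataFrame) -> np.ndarray:
        """Rescaled concentrations aligned to node_order_ (missing genes 0)."""
        if self.rescale:
            scope = self._range_frame(frame).to_numpy(dtype=float)
            if self.rescale_scope == "global":
                lo, hi = self.e_min_, self.e_max_
                lo = np.full(len(frame), lo)
                hi = np.full(len(frame), hi)
            else:
                lo = scope.min(axis=1)
                hi = scope.max(axis=1)
            span = hi - lo
            degenerate = span == 0
            span = np.where(degenerate, 1.0, span)
            values = (frame.to_numpy(dtype=float) - lo[:, None]) / span[:, None]
            values = np.clip(values, 0.0, 1.0)
            values[degenerate] = 0.0
            conc = pd.DataFrame(values, columns=frame.columns)
        else:
            conc = frame
        aligned = conc.reindex(columns=self.node_order_, fill_value=0.0)
        # a gene absent from the matrix enters with concentration 0
        return np.nan_to_num(aligned.to_numpy(dtype=float), nan=0.0)

    def _contributions(self, X) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
        if not hasattr(self, "node_order_"):
            raise RuntimeError("scorer is not fitted; call fit() first")
        frame = self._as_frame(X)
        c = self._concentrations(frame)
        if c.shape[1] == 0:
            zeros = np.zeros((c.shape[0], 0))
            return zeros, (c, zeros)
        d = c @ self.adjacency_.T  # closed-neighborhood sums (A+I)c
        positive = c > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(positive, np.log(np.where(positive, c, 1.0) / np.where(d > 0, d, 1.0)), 0.0)
        # c_i == d_i (isolated / zero neighborhood) gives ln 1 = 0 naturally
        contrib = c * mu
        return contrib, (c, mu)
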