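"""Optional metric-versus-sparsity plots."""

from __future__ import annotations

import pandas as pd


def plot_metric_curves(global_df: pd.DataFrame, metrics=("Cp", "Lp", "Eg", "Eloc"),
                       ax=None, **kwargs):
    """Line plot of global metric curves over the sparsity grid.

    Accepts the table produced by
    :func:`braingraph.metrics.global_metrics_for_stack`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for m in metrics:
        if m in global_df.columns:
            ax.plot(global_df["sparsity"], global_df[m], label=m, **kwargs)
    ax.set_xlabel("sparsity")
    ax.set_ylabel("metric value")
    ax.legend()
    return ax
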