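"""How did the habitat network's connectivity change between epochs?

Builds the complete Euclidean pond network for each epoch (all extant
ponds: 116 then 30), computes each pond's closeness index (mean distance
to every other pond, km; lower = better connected) and, for the surviving
ponds, the change between epochs (positive = became more isolated).

Writes: results/closeness.csv; GraphML exports (large XML) go to scratch/.
"""

from pathlib import Path

import pandas as pd

from pondscape import io, network

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    ponds = io.read_pond_table(ROOT / "case_study" / "ponds.csv")
    nets = {e: network.build_network(ponds, e) for e in ("1957", "2010")}
    close = {e: network.closeness_index(n) for e, n in nets.items()}
    delta = network.delta_closeness(nets["1957"], nets["2010"])
    df = pd.concat(
        {
            "closeness_1957_km": close["1957"],
            "closeness_2010_km": close["2010"],
            "d_closeness_km": delta,
        },
        axis=1,
    )
    df.reset_index().to_csv(ROOT / "closeness.csv", index=False)
    SCRATCH.mkdir(exist_ok=True)
    for e, net in nets.items():
        network.to_graphml(net, SCRATCH / f"network_{e}.graphml")
    print(f"network sizes: {nets['1957'].n} ponds (epoch 1), {nets['2010'].n} (epoch 2)")
    print(f"mean closeness: {close['1957'].mean():.2f} km -> "
          f"{close['2010'].mean():.2f} km")
    print(f"survivors' change: mean {delta.mean():+.2f} km, "
          f"range {delta.min():+.2f}..{delta.max():+.2f} km "
          f"({(delta > 0).sum()} of {len(delta)} became more isolated)")


if __name__ == "__main__":
    main()
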