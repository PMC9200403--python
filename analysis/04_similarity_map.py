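#!/usr/bin/env python
"""Map model-to-target similarity over the (g_AHP, g_GABA-B) plane.

Reference (TAU, LAT) densities are built from simulations at the LPFCm and
MCCm presets (standing in for the recorded populations); each grid cell's
population signature is then scored with the weighted Frobenius similarity
(0.8 Exc-vs-RS + 0.2 Inh-vs-FS). Writes results/similarity_map.csv and the
contour-weighted best-fit coordinates per target.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spikesig.network import (
    build_network,
    population_signature,
    preset,
    simulate_network,
)
from spikesig.similarity import (
    best_fit_from_map,
    bivariate_density,
    network_similarity,
    overall_similarity,
)


def signature_cloud(params, seed, duration):
    m = build_network(params, seed=seed)
    res = simulate_network(params, m, duration, seed=seed)
    tab = population_signature(res, min_spikes=300, n_restarts=20, seed=seed)
    ok = ~tab.excluded
    return (tab[ok & tab.is_exc][["tau", "lat"]].to_numpy(),
            tab[ok & ~tab.is_exc][["tau", "lat"]].to_numpy())


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=300_000.0)
    ap.add_argument("--grid", type=int, default=3,
                    help="grid points per conductance axis")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    targets = {}
    for name in ("LPFCm", "MCCm"):
        exc, inh = signature_cloud(preset(name), args.seed, args.duration)
        targets[name] = (bivariate_density(exc, tag=f"{name}/RS"),
                         bivariate_density(inh, tag=f"{name}/FS"))
        print(f"target {name}: {len(exc)} Exc / {len(inh)} Inh signatures")

    g_ahp = np.linspace(0.022, 0.087, args.grid)
    g_gb = np.linspace(0.0035, 0.0143, args.grid)
    rows = []
    for ga in g_ahp:
        for gb in g_gb:
            p = preset("LPFCm", g_AHP=float(ga), g_GABA_B_scale=float(gb))
            exc, inh = signature_cloud(p, args.seed + 13, args.duration)
            row = dict(g_AHP=float(ga), g_GABA_B=float(gb),
                       n_exc=len(exc), n_inh=len(inh))
            for name, (du, di) in targets.items():
                if len(exc) >= 10 and len(inh) >= 10:
                    s = overall_similarity(
                        network_similarity(du, bivariate_density(exc)),
                        network_similarity(di, bivariate_density(inh)),
                    )
                else:
                    s = np.nan
                row[f"S_{name}"] = s
            rows.append(row)
            print(f"g_AHP={ga:.3f} g_GABA_B={gb:.4f}: "
                  + "  ".join(f"S_{k}={rows[-1][f'S_{k}']:.3f}"
                              for k in targets))
    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "similarity_map.csv", index=False)

    for name in targets:
        s = table.pivot(index="g_AHP", columns="g_GABA_B",
                        values=f"S_{name}").to_numpy()
        if np.isfinite(s).all():
            bx, by = best_fit_from_map(g_ahp, g_gb, s)
            print(f"best-fit {name}: g_AHP={bx:.3f}, g_GABA_B={by:.4f}")
    print(f"wrote {args.out / 'similarity_map.csv'}")


if __name__ == "__main__":
    main()
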