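#!/usr/bin/env python
"""Validate the temporal-signature pipeline on synthetic ground truth.

Fits TAU on OU-rate Poisson trains across generating timescales and LAT /
first-order latency on gamma-renewal trains across shapes; writes
results/signature_recovery.csv and prints the recovery summary.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spikesig.synthetic import gen_ou_poisson, gen_renewal_burst
from spikesig.temporal_signature import extract_signature, first_order_latency


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rows = []
    for tau in (100.0, 300.0, 600.0):
        for rep in range(args.replicates):
            seed = (args.seed * 10_000 + int(tau) * 10 + rep) & 0x7FFFFFFF
            tr, _ = gen_ou_poisson(5.0, tau, 4.0, 600_000.0, seed=seed)
            sig = extract_signature(tr, seed=seed)
            rows.append(dict(kind="ou", true_tau=tau, rep=rep,
                             tau=sig.tau, lat=sig.lat,
                             excluded=sig.excluded))
        got = [r["tau"] for r in rows
               if r["true_tau"] == tau and not r["excluded"]]
        print(f"OU tau={tau:.0f} ms: median fitted "
              f"{np.median(got):.0f} ms over {len(got)} valid fits")

    for shape in (1.0, 4.0, 8.0):
        seed = (args.seed * 77 + int(shape)) & 0x7FFFFFFF
        tr, truth = gen_renewal_burst(shape, 120.0, 600_000.0, seed=seed)
        sig = extract_signature(tr, seed=seed)
        fol = first_order_latency(tr)
        rows.append(dict(kind="gamma", shape=shape, rep=0, tau=sig.tau,
                         lat=sig.lat, first_order_latency=fol,
                         isi_mode=truth["isi_mode"], excluded=sig.excluded))
        print(f"gamma shape={shape:.0f}: LAT {sig.lat:.1f} ms, "
              f"first-order latency {fol:.1f} ms "
              f"(analytic mode {truth['isi_mode']:.1f} ms)")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "signature_recovery.csv",
                              index=False)
    print(f"wrote {args.out / 'signature_recovery.csv'}")


if __name__ == "__main__":
    main()
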