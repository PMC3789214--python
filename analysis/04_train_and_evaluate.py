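#!/usr/bin/env python
"""Train the diagnostic index on visit 2 and predict conversion on visit 1.

Three selection strategies over the corrected-significant features
(median across significant channels): the single best biomarker
(beta peak frequency), the genetic search (PLR survival, 100 generations),
and elastic-net penalized logistic regression (ridge fraction 0.8, 5-fold
CV). Each model is evaluated on the training visit, on the full
evaluation visit, and on the held-out subjects that have no visit-2
recording; the genetic index is additionally stress-tested with
stratified half-split cross-validation.
"""

import argparse
import importlib.util
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import eegdx.classify as classify
from eegdx.statmap import difference_map, reduce_to_features

_spec = importlib.util.spec_from_file_location(
    "diffmap_step", Path(__file__).with_name("03_difference_map.py"))
diffmap_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(diffmap_step)


def metrics_line(name, m):
    plr = "inf" if np.isinf(m["PLR"]) else f"{m['PLR']:.1f}"
    return (f"  {name:28s} SE {m['SE']*100:3.0f}%  SP {m['SP']*100:3.0f}%  "
            f"PPV {m['PPV']*100:3.0f}%  MCC {m['MCC']:.2f}  PLR {plr}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tensors", type=Path, default=Path("scratch/tensors.npz"))
    ap.add_argument("--out", type=Path, default=Path("results/evaluation.json"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    tensors, meta = diffmap_step.load_tensors(args.tensors)
    a, b = diffmap_step.training_split(tensors, meta)
    dmap = difference_map(a, b)

    train_tensors = a + b
    eval_tensors = [t for (s, v), t in tensors.items() if v == 1]
    heldout_ids = sorted(
        {s for (s, v) in tensors if (s, 2) not in tensors})

    def table(ts):
        tab = reduce_to_features(ts, dmap)
        tab["label"] = (tab["group"] == "AD-converter").astype(int)
        return tab

    train_tab, eval_tab = table(train_tensors), table(eval_tensors)
    feats = [c for c in dmap.selected_biomarkers()
             if np.all(np.isfinite(train_tab[c]))
             and np.all(np.isfinite(eval_tab[c]))]
    y_train = train_tab["label"].to_numpy()
    print(f"{len(feats)} usable corrected-significant features; "
          f"training n = {len(train_tab)} (visit 2), evaluation n = "
          f"{len(eval_tab)} (visit 1), held-out n = {len(heldout_ids)}")

    held_mask = eval_tab["subject_id"].isin(heldout_ids).to_numpy()

    def evaluate(model):
        out = {}
        for tag, tab in (("training_visit2", train_tab),
                         ("evaluation_visit1", eval_tab),
                         ("heldout_visit1", eval_tab[held_mask])):
            _, cls = classify.predict(model, tab)
            out[tag] = classify.outcome_metrics(
                cls, tab["label"].to_numpy()).as_dict()
        return out

    results = {}

    single = "beta_peak_freq"
    model_s = classify.fit_logistic(train_tab[[single]], y_train)
    results["single_beta_peak_freq"] = {
        "selected": [single], "metrics": evaluate(model_s)}

    gcfg = classify.GeneticSearchConfig(seed=args.seed)
    sel_g, model_g, trace = classify.genetic_search(
        train_tab[feats], y_train, gcfg)
    results["genetic_search"] = {
        "selected": sel_g,
        "coefficients": dict(zip(model_g.biomarker_names,
                                 np.round(model_g.betas, 3))),
        "metrics": evaluate(model_g)}

    ecfg = classify.ElasticNetConfig(seed=args.seed)
    sel_e, model_e = classify.fit_elastic_net(train_tab[feats], y_train, ecfg)
    results["elastic_net"] = {"selected": sel_e, "metrics": evaluate(model_e)}

    hs = classify.half_split_cv(train_tab[sel_g], y_train,
                                n_iterations=1000, seed=args.seed)
    results["genetic_search"]["half_split_cv"] = hs

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2, default=float) + "\n")

    for name, res in results.items():
        print(f"\n{name} ({len(res['selected'])} biomarkers: "
              f"{', '.join(res['selected'][:6])}"
              f"{'...' if len(res['selected']) > 6 else ''})")
        for tag, m in res["metrics"].items():
            print(metrics_line(tag, m))
    print("\ngenetic index, half-split CV medians:")
    print(metrics_line("half_split_cv", hs))
    print(f"\nresults -> {args.out}")


if __name__ == "__main__":
    sys.exit(main())
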