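"""Walk the three selection stages on the tiny built-in worked example.

The fixture has 12 samples, 2 classes and 8 features: g1 separates the
classes strongly, g2 is an exact affine copy of g1, g3 carries a moderate
signal, and g4-g8 are noise.  Every number printed here is also pinned by
the test suite against independently computed oracle values.
"""

from efsgini import (
    build_cart,
    f_test_scores,
    gini_importance,
    gini_select,
    make_worked_example,
    spearman_redundancy_filter,
)

ds, expected = make_worked_example()
print(f"dataset: {ds.n_samples} samples x {ds.n_features} features, "
      f"classes {ds.classes}")

filtered, report = spearman_redundancy_filter(ds, threshold=0.9)
for dropped, partner, rho in report.dropped:
    print(f"Spearman filter: dropped {dropped} (rho={rho:+.2f} with {partner})")

ranking = f_test_scores(filtered)
print("F statistics (higher = stronger class separation):")
for fid, score in ranking.entries:
    print(f"  {fid}: F = {score:.3f}")

# stage-2 subsets fixed by the fixture: intersection {g1, g3}, k = 3
gs = expected["gini_select"]
res = gini_select(gs["S1"], gs["S2"], gs["S3"], gs["S4"], ds, k=3)
print(f"intersection (kept outright): {res.intersection_features}")
print(f"candidate pool D: {res.candidate_pool}")

tree = build_cart(ds.select_features(res.candidate_pool))
imp = gini_importance(tree)
print("CART Gini importance over D:",
      {f: round(v, 3) for f, v in imp.items()})
print(f"final selection (k=3): {res.final_features}")
print("-> the two consensus features plus the candidate whose tree splits "
      "recover the most impurity")
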