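"""Estimate TTTD and TTNT with the native Kaplan–Meier implementation.

TTTD treats discontinuation/switch/augmentation/death as events; TTNT's
event is the next-line start and death only censors — which is why TTNT
medians exceed TTTD medians.
"""

from claimlines import analyze_bundles, default_config, generate, km_fit

claims = generate(default_config(n_patients=2000, seed=3))
result = analyze_bundles(list(claims.bundles), procedures=claims.procedures)

line1 = result.observations.query("ordinal == 1")
for endpoint in ("tttd", "ttnt"):
    print(f"\n{endpoint.upper()} (first line):")
    for arm, grp in line1.query(f"endpoint == '{endpoint}'").groupby("arm"):
        est = km_fit(times=grp["time"].to_numpy(),
                     events=grp["event"].to_numpy(dtype=bool))
        lo, hi = est.median_ci
        ci = f"({lo:.1f}-{hi:.1f})" if lo is not None and hi is not None else "(n.e.)"
        print(f"  {arm:<12} n={est.n:<5} events={est.n_events:<5} "
              f"median {est.median:.1f} months, 95% CI {ci}")

# The survival curve itself is available as a step function:
grp = line1.query("endpoint == 'tttd' and arm == 'CDK46I_AI'")
est = km_fit(times=grp["time"].to_numpy(), events=grp["event"].to_numpy(dtype=bool))
print(f"\nS(6 months) = {est.survival_at(6.0):.3f}, "
      f"S(12 months) = {est.survival_at(12.0):.3f} on the AI arm")
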