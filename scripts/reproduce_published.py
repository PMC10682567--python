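"""Optional external check: rerun the geographic analysis on the deposited
*Lobelia* dataset.

This script is NOT part of the offline test suite — it needs a local copy
of the publicly deposited occurrence-record CSV (Figshare DOI
10.6084/m9.figshare.23269877), mapped to the package's column schema (see
README). It composes filter -> range model -> marginality -> design -> fit
for *L. inflata* and prints the binary-model coefficient table, plus the
predicted exsertion probabilities at range marginality 0 and 1, for
comparison with the published values (latitude -0.644, marginality -0.222,
longitude 0.286; predicted probabilities 31.3% and 12.9%).

Usage:
    python scripts/reproduce_published.py --input lobelia_records.csv \
        [--mapping schema.yaml]
"""

import argparse

import yaml

from exsertia.covariates import build_design
from exsertia.geometry import build_range_model, marginality_many
from exsertia.inference import fit_glm, predict_surface, wald_table
from exsertia.records import apply_filters, parse_records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", required=True,
                        help="Deposited records CSV (downloaded separately).")
    parser.add_argument("--mapping", default=None,
                        help="YAML mapping canonical -> file column names.")
    parser.add_argument("--species", default="inflata")
    args = parser.parse_args()

    schema = None
    if args.mapping:
        with open(args.mapping) as fh:
            schema = yaml.safe_load(fh)
    records, diagnostics = parse_records(args.input, schema_options=schema)
    print(f"parsed {len(records)} records ({len(diagnostics)} rejected rows)")

    sp_records = [r for r in records if r.species == args.species]
    range_model = build_range_model(sp_records, species=args.species)
    retained, report = apply_filters(sp_records, "binary",
                                     require_elevation=True)
    print(f"binary-model subset: n = {report.n_retained}")
    _, _, r_values = marginality_many(
        [r.longitude for r in retained], [r.latitude for r in retained],
        range_model)
    marg = dict(zip((r.record_id for r in retained), r_values))
    design, params = build_design(retained, "geo_binary", marginalities=marg)
    fit = fit_glm(design)
    print(wald_table(fit).round(3).to_string())
    surface = predict_surface(fit, "z_marginality", [0.0, 1.0], params)
    for _, row in surface.iterrows():
        print(f"predicted P(exsertion) at marginality {row['z_marginality']:.0f}: "
              f"{100 * row['mean']:.1f}% "
              f"[{100 * row['lower']:.1f}, {100 * row['upper']:.1f}]")


if __name__ == "__main__":
    main()
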