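#!/usr/bin/env python
"""Deduplicate the report stream into visits and describe it: distances
to buildings and forest, buildings within 100 m, day/night split, human
presence, foraging success, attractants and event types per species.

Reads results/data/ (from 01_simulate.py), writes
results/tables/visits.csv and descriptive_summary.json.
"""

import argparse
import json
from pathlib import Path

from carnivisit import report_io
from carnivisit.landscape import read_layer


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = report_io.read_reports(args.data / "reports.csv")
    buildings = read_layer(args.data / "buildings.geojson")
    forests = read_layer(args.data / "forest.geojson")

    visits = report_io.deduplicate(records, radius_m=100.0, window_h=6.0)
    print(f"{len(records)} reports -> {len(visits)} unique visits "
          f"({len(records) - len(visits)} repeated observations removed "
          f"by the 100 m / 6 h rule)")
    report_io.write_reports(visits, args.out / "visits.csv")

    summary = report_io.summarize_reports(visits, buildings, forests)
    (args.out / "descriptive_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2))
    for sp, s in summary.per_species.items():
        d = s.dist_building_m
        print(f"{sp}: n={s.n_reports}, median distance to building "
              f"{d.get('median', float('nan')):.1f} m "
              f"(IQR {d.get('q1', 0):.1f}-{d.get('q3', 0):.1f}), "
              f"day fraction {s.day_fraction:.2f}, "
              f"feeding success {s.success_fraction:.2f}")


if __name__ == "__main__":
    main()
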