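# odflow

Analyze intermunicipal patient journeys as directed, weighted, geolocated
networks. From hospitalization records (origin municipality, destination
municipality, procedure, competence year/month), `odflow` builds yearly
origin–destination matrices and flow networks and computes, for a focal
municipality, six journey indices per year:

- **in-degree / out-degree** — number of distinct municipalities sending
  patients to / receiving patients from the focal municipality;
- **incoming / outgoing flow** — total journey counts on those arcs;
- **mean length of incoming / outgoing arcs (km)** — the flow-weighted
  average straight-line distance of the arcs,
  `D̄ = Σ_a D_a·F_a / Σ_a F_a`, reported as `NA` when the corresponding
  degree is zero.

Distances are straight lines, either Euclidean in UTM plane coordinates
(WGS84 transverse Mercator, implemented in-package) or great-circle
(haversine, mean radius 6371.0088 km). Networks export to GEXF/GraphML
with geographic node attributes for Gephi-style spatial layouts. A seeded
gravity-model generator (Poisson flows with exponential distance decay)
produces synthetic registries and record files so the full pipeline is
testable without any external data.

## CLI

```bash
# 1. generate a synthetic scenario (registry.csv + records.csv)
odflow synth --n-municipalities 50 --providers 290001,290002 \
             --years 2008-2020 --theta 6 --decay-km 250 --seed 1 --out data/

# 2. build per-year networks: edge lists, OD matrices, GEXF files
odflow build --records data/records.csv --registry data/registry.csv \
             --years 2008-2020 --distance utm --out out/

# 3. per-year index table (Table-1 style CSV) for a focal municipality
odflow indices --records data/records.csv --registry data/registry.csv \
               --focal 290001 --years 2008-2020 --out out/

# 4. one-off export of a single year
odflow export --records data/records.csv --registry data/registry.csv \
              --year 2020 --format graphml --out out/
```

All flags can instead come from a YAML config file (`--config run.yaml`);
explicit flags override file values. Real-world record files with other
column names (e.g. SIH RD exports) are supported through a schema mapping
in the library API (`read_records(path, schema=...)`); procedure-code
filters are newline-delimited text files passed with `--procedures`.
Every command writes a `run_manifest.json` with inputs, parameters and
counts beside its outputs.

### Input formats

- records CSV: `year,month,origin_code,dest_code,procedure_code`
  (comma or semicolon delimited, UTF-8 or Latin-1; 7-digit IBGE codes are
  normalised to their 6 significant digits);
- registry CSV: `code,name,lat,lon[,easting,northing,utm_zone,macroregion]`
  (lat/lon in decimal degrees; UTM triple optional but all-or-none).

## Library

```python
import odflow

result = odflow.read_records("records.csv")
registry = odflow.read_registry("registry.csv")
records = odflow.filter_by_procedure(result.records, odflow.ProcedureFilter({"0406010013"}))

net, report = odflow.records_to_network(records, 2020, registry)
row = odflow.index_row(net, focal="293330")
bd = odflow.macroregion_breakdown(net, "293330", "incoming")
```

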