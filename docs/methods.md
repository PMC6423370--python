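# Methods

## System model

A deployment is a rectangular grid of plots (0-based row-major coordinates,
row 0 at the north edge), each plot carrying genotype / treatment /
replicate metadata and at most one monitoring device. Devices operate
autonomously: they log one reading per sensor variable per hour, capture a
few images per day, and synchronize with a central collation server.
Storage on both sides shares one SQLite schema (experiments, plots,
devices, readings, images, status snapshots). All timestamps are stored
and exported as UTC ISO-8601 at second resolution; deduplication equality
is at second resolution, which is ample for hourly/half-hourly cadences.

## Representative-image selection

The day's captures are scored on three criteria:

- **file size** — a hard gate (`min_file_size`, default 0 i.e. disabled;
  deployments typically set it relative to the day's median size). Rejects
  truncated or empty files.
- **mean intensity** — a hard gate with default window [40, 215] on the
  0–255 grayscale, rejecting dark and blown-out frames. The bounds are
  deliberately permissive; the window is configurable.
- **clarity** — the objective: variance of a 3×3 discrete Laplacian of the
  grayscale image. Defocus suppresses second derivatives uniformly, so
  Laplacian variance is a standard no-reference sharpness proxy. A flat
  frame scores exactly 0.

Selection is gates-then-argmax: among images passing both gates, the
maximum-clarity image wins, ties broken by earliest capture time. This
composition is the simplest one that makes the three criteria independently
testable; the selection is provably equal to exhaustive search (the test
suite checks this against a brute-force oracle on randomized candidate
sets).

## Downsizing

Representatives are downsized from 2,592 × 1,944 to 640 × 480 — a
non-integer 4.05× factor — by exact area-averaged (block-mean) resampling:
each output pixel is the overlap-weighted mean of its fractional source
footprint, implemented as two row-stochastic weight matrices applied per
channel. Because every source pixel contributes total weight 1/scale, the
global mean is preserved to floating point before the final 8-bit rounding
(hence within one gray level end to end). Aspect-ratio mismatches are an
error rather than a silent crop or stretch.

## Sync protocol

One sync = one JSON document: the latest status snapshot, every reading
strictly after the `since` cursor, and the newest not-yet-acknowledged
representative image (base64-embedded). The canonical serialization (keys
sorted, no insignificant whitespace) is signed with HMAC-SHA-256 under the
device's pre-shared key; the server verifies before parsing and parses
completely before storing, so a tampered or malformed document leaves the
store untouched. Ingestion is idempotent by construction — readings,
images, and status snapshots are all keyed by (device, instant) — and the
ack carries the highest ingested reading timestamp so the agent can advance
its delta cursor.

Store-and-forward: undeliverable payloads enter a FIFO queue (optionally
persisted as sequence-numbered JSON files so it survives agent restarts).
On reconnection the queue drains oldest-first before the current payload.
Entries older than the retention horizon — 60 days by default, the capacity
of the device's onboard buffer — are dropped with a logged warning, as is
the oldest entry when a capped queue overflows. The guaranteed property,
exercised end-to-end in the tests, is partition recovery: for any outage
pattern that ends before the run does, the final server dataset equals the
outage-free run's byte for byte (restricted to data within the retention
horizon).

## Device health classification

Green / amber / red is a pure function of the latest snapshot's mode and
the silence time relative to the expected update cadence (30 minutes by
default, matching the shipped status-refresh interval):

- red — mode is `error` or `terminated`, silence > 6 cadences, or no
  contact ever;
- amber — mode is `idle`, or silence > 2 cadences;
- green — otherwise.

The multiples keep the rule cadence-agnostic; the classification is
monotone in silence (a device never improves by staying quiet). Uptime is
latest image capture time minus boot time, zero before the first capture; a
capture predating boot is reported as clock skew, never clamped.

## Grid interpolation

Unmonitored plots are filled by inverse-distance weighting with power 2
over all sensor plots, using Euclidean distance in grid coordinates; a
sensor plot's own value is the mean of its readings within ±12 h of the
frame instant (the window is a parameter — the temporal aggregation used
for presentation is not uniquely determined by the underlying data model,
so it is exposed rather than fixed). IDW's convex weights give three
testable guarantees: exactness at sensor plots, boundedness by the measured
range, and translation equivariance. Kriging or variogram-based methods are
deliberately out of scope; with 16 sensors on a 4×8 grid there is too
little data to fit a variogram defensibly, and IDW's guarantees are what
the monitoring views rely on. Leave-one-out validation predicts each sensor
from the others under the same scheme and reports per-sensor errors plus
RMSE; RMSE shrinks to zero as the spatial field flattens.

Heat-map series default to 14-day frame spacing — the conventional cadence
for summarizing a growing season — with sensor plots outlined red and
interpolated plots green, and a color scale fixed across the series.

## Late-blight risk rule

A day qualifies iff its daily minimum temperature is ≥ 10 °C **and** at
least 11 of its 24 hours have relative humidity ≥ 90%; a risk period is a
maximal run of ≥ 2 consecutive qualifying days. All thresholds are
inclusive, matching the rule's "or above" / "at least" phrasing; the daily
minimum is taken over all 24 hourly values, so the per-day decision is
order-free within the day. Days are calendar days in the caller's chosen
timezone (`tz` parameter; storage stays UTC). Partial days are excluded
with a warning rather than guessed. The detector is validated against an
exhaustive run-scan oracle on 1,000 randomized months whose temperatures
and wet-hour counts straddle both gates.

## Field simulator

The generator emulates the study conditions the package is designed for:
the standard layout is 16 monitored plots among 32 genotype plots on a 4×8
grid; devices log 6 variables hourly, capture 3 images/day, and sync
hourly, with status refresh configured at 30 minutes.

Weather is closed-form plus noise: ambient temperature is a sinusoid
(default mean 15 °C, amplitude 5 °C — typical of a temperate growing
season — minimum at 02:00, maximum at 14:00) with a linear seasonal trend
(default +0.05 °C/day); relative humidity runs anti-phase (base 75%,
amplitude 15%); light is a solar half-sine (6:00–18:00, 60 klx peak), zero
at night; soil temperature is ambient lagged 2 h and damped by 0.5 toward
the seasonal baseline; soil moisture is a noisy constant. Humidity and
soil moisture are clipped to [0, 100] after noise. Noise is i.i.d.
Gaussian per variable with small defaults (0.3–3 in each variable's
units). Every stream derives from a master seed plus a stable
per-device / per-variable key (SHA-256 of the name), so runs are fully
deterministic and composable: adding a device never changes existing
devices' data.

Synthetic images are procedural canopy-like textures (smoothed random
blobs plus fine detail) in which clarity is strictly increasing in the
`sharpness` parameter and mean intensity in `exposure`; an optional
bad-frame rate injects near-black captures to exercise the selection gates.

What the simulator does **not** emulate: radiative or energy-balance
micrometeorology, rain events and their correlation structure, crop growth
or phenology in the imagery, sensor drift/bias, or realistic network
pathologies beyond clean outage windows. Passing tests therefore
demonstrate the correctness of the data-management contracts (selection,
transport, idempotency, interpolation algebra, rule detection) on data with
realistic structure — not meteorological fidelity.

## Numerical and design choices

- Problem sizes in the test suite: the heavyweight end-to-end property
  runs 10 devices × 30 days at a proportionally reduced capture resolution
  (192 × 144, preserving the 4:3 ratio); the oracle-equivalence checks use
  1,000 randomized instances each. These sizes exercise every code path
  (multi-day outages, queue drain, day closure) while keeping the suite
  fast to iterate on.
- CSV dialect: comma, header `device_id,variable,timestamp_utc,value`, LF
  endings, `repr` floats (shortest round-tripping form). Zip entries are
  named `<device_id>/<YYYYMMDDTHHMMSSZ>.<ext>` with fixed entry mtimes and
  compression level, so both exports are pure functions of store content.
- The agent advances its reading cursor at payload-build time, so queued
  payloads carry disjoint deltas; a payload dropped at the retention
  horizon loses exactly its own data, which is what bounds the recovery
  guarantee.
- The server stores all synchronized images (the representatives devices
  upload); full-resolution capture series remain on the device side.
- Degenerate inputs: an empty candidate set or all-gated day yields no
  representative (the day simply has none); an interpolation instant with
  no readings anywhere raises rather than fabricating a grid; correlation
  on constant series is an explicit degenerate-series error.

## Known limitations

- IDW over grid coordinates ignores real-world plot spacing anisotropy;
  if row and column pitches differ materially, distances should be scaled
  before interpolation.
- Health classification trusts device-reported snapshot timestamps; a
  device with a skewed clock can look fresher or staler than it is (skew
  is surfaced only via the uptime check).
- The HTTP facade is a thin development/deployment server (stdlib
  `http.server`), not a hardened public endpoint; authentication protects
  payload integrity, not transport privacy (no TLS).
- Queue eviction logs but does not alert; a deployment would want the
  delivery reports wired to monitoring.
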