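# metroaccess

Travel-time accessibility of health services across metropolitan area
typologies, compared between private vehicles and public transport.

## The problem

Health-planning audits of large metropolitan areas routinely ask how long
residents must travel from home to their nearest health service, how that
time differs between a car trip and a walk-plus-transit journey, and how
both degrade from the inner city out to newly developing fringe suburbs.
The canonical framing uses a case-study chronic condition — type 2
diabetes, which requires regular visits to eight service types: six
*primary* services needing no referral (GP, pharmacy, optometry,
podiatry, physiotherapy, dietician) and two *secondary* specialist
services (diabetic educator, endocrinologist) — and classifies the
metropolitan area into five typologies: **inner**, **middle**,
**outer established**, **outer growth** and **outer fringe**.
A companion policy yardstick is the *20-minute city*: essential services
reachable within a 20-minute journey from home.

`metroaccess` implements that audit as a fully testable pipeline.  A
seeded generator produces a synthetic concentric-ring city with the
statistical structure the analysis assumes (centre-weighted facilities,
a hierarchical road lattice, transit that thins outward, uniform random
addresses per ring), so every stage runs with no proprietary GIS data.

## The model

**Private vehicle.** Each road edge carries one of five hierarchy
classes.  Off-peak driving speed per class is estimated as

- the mean of observed inner- and outer-region off-peak speeds when both
  are available: freeway (100 km/h signed) → (70+80)/2 = **75 km/h**;
  arterial (80) → (32.5+43)/2 = **37.75**; sub-arterial (60) →
  (28+38)/2 = **33**;
- half the sign-posted limit when unmeasured: collector (50) → **25**;
  local (40) → **20** — the ≈½ ratio observed on the measured classes.

Edge time is `length / speed`; the OD (origin–destination) entry for an
address and a service type is the shortest-path minimum over all
facilities of that type, via multi-source Dijkstra on the undirected
network.

**Public transport.** A journey alternates walking legs (road network at
5 km/h by default) and timetabled vehicle legs boarded no earlier than
their scheduled departure.  For a fixed departure instant (Wednesday
12:00 noon by default) the earliest arrival is computed by a
connection-scan over departure-sorted ride legs with an all-pairs walking
matrix for transfers; the journey time includes the initial wait and
never exceeds the pure-walk time.

**Summaries.** Per (typology × service × mode): n, median, quartiles,
min/max, and the count of unreachable cells; public−private median
differences and public/private median ratios; median gaps relative to the
inner typology; and the share of addresses within 20 minutes.

## Worked example

```python
import pandas as pd
import metroaccess as ma
from metroaccess.road_model import default_speed_model

net, feed, fac, addr, _ = ma.generate_city(ma.CityConfig(seed=42))
od_car = ma.private_od_times(net, default_speed_model(), addr, fac)
od_pt  = ma.transit_od_times(net, feed, ma.WalkParams(), ma.DepartureSpec(), addr, fac)
summary = ma.summarize(pd.concat([od_car, od_pt], ignore_index=True))
gaps = ma.mode_gap(summary)
print(gaps[gaps.service_type == "endocrinologist"].round(2).to_string(index=False))
```

prints

```
         typology    service_type  median_private  median_public  median_diff_min  median_ratio
            inner endocrinologist            2.27          12.00             9.73          5.30
           middle endocrinologist            4.82          24.28            19.46          5.04
outer_established endocrinologist            8.52          39.28            30.76          4.61
     outer_fringe endocrinologist           16.16          66.71            50.55          4.13
     outer_growth endocrinologist           11.82          56.71            44.90          4.80
```

Reading: on this synthetic city the median drive to the nearest
endocrinologist grows from 2.3 minutes (inner) to 16.2 minutes (outer
fringe), the median transit journey from 12 to 67 minutes, and transit is
4–5× slower than driving in every typology — the access gradient and
mode gap the audit is designed to expose.  The corresponding 20-minute
audit (`ma.twenty_minute_share`) shows specialist care within 20 minutes
for essentially all inner-city addresses by either mode, but for only
8–14 % of outer growth/fringe addresses by public transport.

The same pipeline is available from the shell:

```bash
metroaccess run-all --seed 42 --out run42        # whole pipeline + manifest
metroaccess generate --seed 42 --out city        # city artifacts only
metroaccess route-private --network city/network \
    --facilities city/facilities.geojson --addresses city/addresses.geojson \
    --out od_private.csv
metroaccess audit-20min --od od_private.csv --threshold 20 --out audit.csv
```

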