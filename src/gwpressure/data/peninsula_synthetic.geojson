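{
 "type": "Feature",
 "properties": {
  "name": "synthetic peninsula fixture",
  "note": "Synthetic coastal-peninsula outline in a projected metric frame (units: m). Not real cartography; shaped to yield both full and undersized 10 km grid cells.",
  "crs_id": "synthetic-metric"
 },
 "geometry": {
  "type": "Polygon",
  "coordinates": [
   [
    [
     2000.0,
     88000.0
    ],
    [
     9000.0,
     83000.0
    ],
    [
     7000.0,
     76000.0
    ],
    [
     12000.0,
     70000.0
    ],
    [
     10000.0,
     62000.0
    ],
    [
     15000.0,
     55000.0
    ],
    [
     13000.0,
     47000.0
    ],
    [
     18000.0,
     40000.0
    ],
    [
     17000.0,
     31000.0
    ],
    [
     23000.0,
     24000.0
    ],
    [
     22000.0,
     16000.0
    ],
    [
     27000.0,
     9000.0
    ],
    [
     33000.0,
     2000.0
    ],
    [
     39000.0,
     6000.0
    ],
    [
     41000.0,
     15000.0
    ],
    [
     38000.0,
     22000.0
    ],
    [
     44000.0,
     28000.0
    ],
    [
     42000.0,
     36000.0
    ],
    [
     48000.0,
     43000.0
    ],
    [
     46000.0,
     52000.0
    ],
    [
     52000.0,
     58000.0
    ],
    [
     50000.0,
     67000.0
    ],
    [
     55000.0,
     73000.0
    ],
    [
     53000.0,
     81000.0
    ],
    [
     57000.0,
     87000.0
    ],
    [
     30000.0,
     91000.0
    ],
    [
     2000.0,
     88000.0
    ]
   ]
  ]
 }
}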