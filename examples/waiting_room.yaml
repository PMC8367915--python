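# Dental waiting-room comparison: four designs, all measuring Mon-Fri,
# differing in clusters per condition (k) and trial length (R weeks).
m_range: [1, 20]
rho: 0.05
r: 0.95          # decay 1 - r = 0.05 per calendar day
d: 0.2
alpha: 0.05
sided: two
t_max: 56        # data must be in within 8 weeks
dropout:
  control:      {omega: 0.2, gamma: 2.0}
  intervention: {omega: 0.1, gamma: 2.0}
designs:
  - {scheme: "Mo,Tu,We,Th,Fr", weeks: 4, clusters: 10}
  - {scheme: "Mo,Tu,We,Th,Fr", weeks: 4, clusters: 15}
  - {scheme: "Mo,Tu,We,Th,Fr", weeks: 8, clusters: 10}
  - {scheme: "Mo,Tu,We,Th,Fr", weeks: 8, clusters: 15}
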