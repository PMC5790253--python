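code,indicator,level,color,note
G1,Access to the fishery,open_access,red,open access erodes stewardship incentives
G1,Access to the fishery,permits,green,limited-entry access right
G1,Access to the fishery,turf,green,territorial use rights foster stewardship
G1,Access to the fishery,quotas,green,catch shares limit effort
G2,Number of fishers,increasing,red,growing effort raises pressure on the reserve
G2,Number of fishers,stable,green,stable effort
G2,Number of fishers,decreasing,green,declining pressure
G3,Legal recognition of reserve,yes,green,formal recognition strengthens enforcement
G3,Legal recognition of reserve,no,red,unrecognized reserves are harder to defend
G5,Illegal harvesting,none,green,no poaching pressure
G5,Illegal harvesting,low,green,poaching pressure is minor
G5,Illegal harvesting,medium,red,material poaching pressure
G5,Illegal harvesting,high,red,heavy poaching undermines protection
G6,Management plan,yes,green,written management plan exists
G6,Management plan,no,red,no management plan
G8,Size of reserve,adequate,green,large enough for the target species' mobility
G8,Size of reserve,inadequate,red,too small to protect target species
G10,Membership to fisher organizations,yes,green,organized fishers cooperate and self-police
G10,Membership to fisher organizations,no,red,no collective organization
G11,Type of fisheries organizations,cooperative,green,cooperatives support co-management
G11,Type of fisheries organizations,federation,green,federated cooperatives add bargaining power
G11,Type of fisheries organizations,none,red,no organizational structure
G12,Representation,high,green,inclusive bottom-up reserve design
G12,Representation,medium,red,partial participation in decisions
G12,Representation,low,red,decisions exclude most fishers
G13,Internal Regulation,yes,green,internal rules control effort
G13,Internal Regulation,no,red,no internal rules
G14,Perceived Effectiveness,positive,green,community perceives the reserve as working
G14,Perceived Effectiveness,neutral,red,no perceived benefit
G14,Perceived Effectiveness,negative,red,reserve perceived as failing
G15,Social Impact of Reserve,positive,green,reserve builds social capital
G15,Social Impact of Reserve,neutral,red,no social benefit perceived
G15,Social Impact of Reserve,negative,red,reserve causes social conflict
S3,Alternative economic opportunities,many,green,livelihood diversification buffers closures
S3,Alternative economic opportunities,some,green,partial diversification
S3,Alternative economic opportunities,few,red,community depends on the fishery
S3,Alternative economic opportunities,none,red,no alternatives to fishing income
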