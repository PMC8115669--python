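# mrmkit-transitions v1
protein,peptide,label,q1_mz,q3_mz,fragment,collision_energy_V,cone_voltage_V,rt_min,role
CC16,EAGAQLK,native,358.9,516.6,y,10.0,30.0,4.5,quantifier
CC16,EAGAQLK,labelled,362.9,524.6,y,10.0,30.0,4.5,quantifier
CC16,EAGAQLK,native,358.9,260.5,y,7.0,30.0,4.5,qualifier
CC16,EAGAQLK,labelled,362.9,268.5,y,7.0,30.0,4.5,qualifier
RBP4,YWGVASFLQK,native,599.6,849.7,y,9.0,30.0,8.4,quantifier
RBP4,YWGVASFLQK,labelled,603.6,857.7,y,9.0,30.0,8.4,quantifier
RBP4,LIVHNGYCDGR,native,435.2,539.6,y,9.0,30.0,5.5,qualifier
RBP4,LIVHNGYCDGR,labelled,438.5,544.6,y,9.0,30.0,5.5,qualifier
B2M,VNHVTLSQPK,native,375.0,244.3,y,20.0,30.0,5.3,quantifier
B2M,VNHVTLSQPK,labelled,377.7,252.3,y,20.0,30.0,5.3,quantifier
B2M,VNHVTLSQPK,native,375.0,459.0,y,12.0,30.0,5.3,qualifier
B2M,VNHVTLSQPK,labelled,377.7,467.3,y,12.0,30.0,5.3,qualifier
OPN,GDSVVYGLR,native,483.3,607.2,y,15.0,30.0,6.4,quantifier
OPN,GDSVVYGLR,labelled,488.3,617.2,y,15.0,30.0,6.4,quantifier
OPN,GDSVVYGLR,native,483.3,508.2,y,15.0,30.0,6.4,qualifier
OPN,GDSVVYGLR,labelled,488.3,518.2,y,15.0,30.0,6.4,qualifier
HSA,SLHTLFGDK,native,340.0,319.3,y,12.0,30.0,6.7,quantifier
HSA,SLHTLFGDK,labelled,342.7,327.3,y,12.0,30.0,6.7,quantifier
HSA,SLHTLFGDK,native,340.0,466.3,y,12.0,30.0,6.7,qualifier
HSA,SLHTLFGDK,labelled,342.7,474.3,y,12.0,30.0,6.7,qualifier
HSA,HPYFYAPELLFFAK,native,581.9,483.1,y,15.0,30.0,9.0,qualifier
HSA,HPYFYAPELLFFAK,labelled,584.6,487.1,y,15.0,30.0,9.0,qualifier
MYO,HGATVLTALGGILK,native,451.0,367.6,b,10.0,30.0,8.2,quantifier
MYO,HGATVLTALGGILK,labelled,453.7,367.6,b,10.0,30.0,8.2,quantifier
MYO,HGATVLTALGGILK,native,451.0,487.6,y,16.0,30.0,8.2,qualifier
MYO,HGATVLTALGGILK,labelled,453.7,495.6,y,16.0,30.0,8.2,qualifier
NFKB,LPPVLSHPIFDNR,native,502.3,648.1,y,12.0,30.0,7.4,quantifier
NFKB,LPPVLSHPIFDNR,labelled,505.6,653.1,y,12.0,30.0,7.4,quantifier
NFKB,LPPVLSHPIFDNR,native,502.3,289.4,y,20.0,30.0,7.4,qualifier
NFKB,LPPVLSHPIFDNR,labelled,505.6,299.4,y,20.0,30.0,7.4,qualifier
BSA,LGEYGFQNALIVR,native,740.9,813.8,y,30.0,30.0,7.9,quantifier
BSA,LGEYGFQNALIVR,labelled,745.9,823.8,y,30.0,30.0,7.9,quantifier
BSA,LGEYGFQNALIVR,native,740.9,1018.2,y,30.0,30.0,7.9,qualifier
BSA,LGEYGFQNALIVR,labelled,745.9,1028.2,y,30.0,30.0,7.9,qualifier
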