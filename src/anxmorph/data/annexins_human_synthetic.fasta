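>ANXA1|NP_000691|synthetic
LRGGESDFHLWKKRIFFCLANKAGRMTICNDEFHQNSKGNDVLYMAPVGRMQMKDLPIQQ
APDWELTNAPTFTYFAQRCDEHRVKWLNSLIWNYSPLKCEQHAPQFQQAFQFCALYWFEI
IYDFNGMGVDFECVYLFAHFMSRTCPWYSQQVVICWMGHGCQIRFHIHKPTEVGAKQTPH
RTWVVNFRLNNTQTSIYEQRCLLHGRYWTIDNYPMDKLNQDVGTVGNMMFIVVRGYGQFQ
WYRAWFQNMFLCENAKAPGMQRMHKCGKIRCSDEQGNESLLYYLQDTGGCLYNAPPTESV
PNWTWYEIHSWMGTEPSVTPMQDDFMFSPDITNVECPGMYVDAKSR
>ANXA2|AAH68065|synthetic
LRGGESCFHLWVRRIFFGMTICNDEFHQNSKNNDVLYMAPVGTMSMKDLPISQFPQWEFT
FADTFTYKLQRCDTHLVKWLNALIWNYSYKKHEQHAPLFCQCFQHCALYWMEIQFMFVGM
GVDFECNYDFAHFMSRTCPVSAQQVVWCWMHHGWTPRFYIHKPTEVRAKQNPHRTWVVNP
QLGNHQTAICEMFCLLHGRYATIDTYPMDLLNQDVGTVGRAMEINVREYKHFHGKRKWFQ
NWFCCENNKAPFMQRMHKCLKIRCSSEPGNESMLCYLLDTGGSLYNAPPMEEVPNWTWYC
IKSWMGTEVSVKPCDDDHYFSPDHTNVECWGLAVDNKSR
>ANXA3|NP_005130|synthetic
PWPISGIRDFFQNFKNNDELVMHPNGRPSMKDLPASQAPQMKRTWSDTFTCMDQRFDAAL
DQWLNAYNWQYGPIVSGTFVPDFQLGWQTCAMYCCEIQVMFNVNGTSENCNYDSPHPRTR
FCGVPNQGAAFRWQCMGTPPRFYIKRCTEVLHDQVMHREVVFAPRGGMKYEANDENHCIL
HGTNATLETYPMTPRRLRVGSVTNCMFIESYPQKQFQSKRAEQPNCHHCNVFGNKDDARL
LNCGRCRQIADQRNEFLLGKPSQDGGHLGVNPMHEHDPNWRMAEIPSWTYCWVSQTRMQG
QFMFPPDIQNPGCIKTAPDGKSK
>ANXA4|EAW99844|synthetic
WHNDHGLPNFKNWTVYVLHPNGCMKMKLLPSSQIEQMEDTNADTFTPMDQRCDFELDNWR
PALNWMISPNCSGQDSPLFQTGPMMCARYWRHSQFMCQGMGVSYNCAYDFPHPRQDKCQV
PAQSVAWCWMCHGTWPNDYIRWPTEVLAPQVVHRETVVAPELGQKSEAIDEKHCFLHGTN
LAIETYARMPISVREGTQGNMWFNELNAQGQFQGKLAMFPGQFLMENNKNPPDFRVKNCY
KWRQSHDQGNTSQLWALIPGGGHLGNQWMHEEKPKWARGVNDRWTPTWVQVTPQQGLFMF
TCTYQNVRCPKVKIDNESW
>ANXA5|NP_001145|synthetic
CTWANDHHQPNFKNVHVLVMHPNGRMKMKLLPSSQAEQWEDTNADTFTCMDQVCDFDLDN
GTPALNWDYSPNKFGQWAILFQTGWMMCALYCCHSQFMEWGMGVSYLCNYDFPHPRQRWC
QVPAQSLAGCWMFHGTWPRLYCRKPTEVDRPQVVRRETVEAPRLGCKYEAIDEAHYYLHM
TNVVIETYAMMPIRTREGTVGNMWFIECNAQGQFQGKQAMIKNQFYLENNKCKPDARNKN
CYKWRQSTDQGNASLTCKLSEGGGHLGNQSMLAEYPNWARGVIDSTTPTWVSPTPQCHLF
MFTPWVQNVPCPKDAIDNESW
>ANXA6|AAH17046|synthetic
CKCFFNLTKANIVAMICYYTLTMAHDSPFQMFFNGEVLFCISLFCKSMRDMPQSQKLWWA
RDWADKFTDVGQWCYHPLDNKLNALNIKIVYGLSDQRFPLFFPVWFMCWLYVCPLCWMDK
NRKVDTYGCYSFVPPGERRVPPYAQSVAWCWMSHNQPPNDEIYTPTEKHAYQAWHREWPV
NPRLTYKCHAEIVIHCNLMGQEAGAKGPPMDRTSQRPICGPDGHFISQHAQKQFRGWWIW
VQMYFFIEFNCVPCDERALYILVQRQLNDQGHSSIYHKLVDLGIFLNEQMMPEMREEHTK
DEGVPWMTHEGPVLPMQGLFMGWPDTQPWRYFSERTQNQQFGKRHLVSMRRDSWIINSLN
APMFDNTFVLDMHRLWEMMMPDRLWSDAPQGMHTPCRTETHVDQSYCHHLKMFLVTLLWP
HRRWNSMGHGQLFQDASVICWLYAAGIFCLFVKPGPRFTPNYDCSLHWWRTGPDRAQIKA
FRRNCAPTPPDVAIKTKQVGLAPQMVRRGTVVNPDAEVWQINLIEYDAGAMMLLMSRQHP
RTLPCRKRTKCVGGSRHERDRAIKDNRGGVWWFRNMFCWASLCADCDHRMLCLLVDFPSA
VGNNLEYYQYLCGEGMMLANAPMHEYVKDDIGREQESWEPHTYIRNEFHENCGGWECTQQ
VGLYQDRRDNHIK
>ANXA7|AAH02632|synthetic
DMFKTKEALPDKYMKSPKHLHWTQKCILISNANNQPPPRIDKAERGHAQTKQLCIDDITF
HKQLSHGQCEVNNEYYHVLIQVEWAADCTCALTYPDLPFFMRHYCWVHFRNKHHCHSPNS
TDDKHYLRTKIFDIHGPACEMMKNDRRSFSYKEHLEENMYNGHIMHIETWHADAKFQMFE
DCYVKVYHPLGRNSMKYHCIGQAPCRHWANWDTFNGMRQRHDFTLDCWRNQLVWPYSPMY
SMQHAPLTQQASQARQDKWCEWIWMWCGMGVNVNNNHDEMKPTQPTCPVYAGWVANCYMC
HKSPPRFYIYKPIHQLAHQLVKEEWVINSVLKNWQEAIWEYLCMIHGENAHIKKRPMDPH
RDDDGLVGNMMTEEWCAIKQFRGVRCTFPDISLCYNAKAPPDYRGLNCLVCRQVFTDGNF
SLLGCLLDLGPHLGNQPMHYECPRGTMAEIDWWMPTEVPATPHQGLHQFTHQIQCVRCPH
TTIDNESI
>ANXA8|AAH73755|synthetic
DNQGMTTVLHNPQFFQMFKNNYMDMTHPLGRMSMKKHPIKQAPQWEIANFMTSHGMDQRC
DHDLDLWFQALNYPYSEGKSMQCRPLKTQGWQMRAWYCCEIWKMFSGMGTWYNENYDFMY
PTIGTCPVYAQPVFWKWMCHITPLRFYIKKTIHALAPQVVDRTRGKNPEEGNIQESIWEY
HCLLRGWNAMCFMLPMDPHENEDGTVGNGMFMEVRAGKQFRGDQAVIWMGYLQEDPKAPG
DENCLNMALCSQSFDQCMHSQLGGCSDLVGHTYNASADEEYPRWWMAEIDSFMPTEVPAT
PMECEPMKTTPIWCVRCPHDANFNRSK
>ANXA9|NP_003559|synthetic
KETYSHSRNKIPEKECKCYYMHCYDRIKNEQFHMNFKNWDVLVEPPYGSMSNKDLPIDQA
CQWRGFNADTFTGKDQRQDGHVSKPLNAVIWNESPEERHQWAQLFQQGFIDCFLYWEEPI
PMFNGMGVDYFCMYDFDHWMSRNCPVYDQSVAWTWQCDVFTPCFYIEGPTEVDAPMTSHR
TNVDNPRLGNGWWAIFEQRKMLHGRNNTIDTYPMDLIANRQGIVGNMWFQEQRILIQFQG
KRWLGVNMFLIEANEAPPDQAMDMCHKNICSHDGENENLIGKLSDDGGHLRNPIPWEEYP
NWTMYVIDSNIPTSVSVTNMQFLFMGTPDICNVQCPADATDHKMK
>ANXA10|NP_009124|synthetic
LCCKTWHNIQFFQLFKKNWVLLMHPLGRMSMSDLDIGQFPQWEWTIKQTIKRITGLGDHH
DDNWLNMIEFWYSPTESMTHAYLFSFGWMMEEWYCCEIQVMKNGMGVTYNCCNDFAQPQQ
NYAPVYSQDMANCIMCHWVPPRFNIIFPIEVLVSQVHHRIYVWNTWLCNWGTKIFEYEAH
YHGCNITIKGPPSDPPGPLVGKFQVMKFIQVSKQKTFVGARFGFKNYFLCENMKTPPEEP
CLKMLRFCQQVHQGNESIDGGLSDLGSHLGNAPPHEEYPPMDMQYITSWPPTEQVVNSWE
GLKDFTNFIYCFRCPHDWIDNMFP
>ANXA11|CAB94997|synthetic
DMVKMYEWLPDKGMKTPYHLHTTQKVIPISNSNNQPPPVIGKNERGHTQTNCLCIDGKTF
DKQTSHIAPEVNIEYYHVLIMVEWAADITQTLSYPDLEFFMRHYYNMHMRAKDNCFSPNI
TFDALYAKTKIFFIHGIACNIHMNDRGSSSQKEWLEENMYRGRTPTKEAPCDAIFISHPD
VCLFQTWHAYQFQQSFTDCYVAHYHPLGRMWCKYNPINQAPCIEIHNDDTFNGTRQRCLL
ELNMWRNQLVWPYPPMMSMQHAGLFRQAWQARQDHRCSIIWVFCIMGVNGLCNYDSMKPP
QRQQPVYAGWVANCIMCHAGGPRFMIKKPGHQLAHRLVKEEWVVNSVLKNWQEAIELYHC
CIYGRHAAFKTPPMDAHGQRDGLIGNMPTEEWRAIKQFRGKRAKKPVISLCYNNKAIPDE
RMQNCQVCRQVFDDGNEHLCGLLNDLGGHLGNAPMHYECPRWWMAYIDQWMPTEVPETPH
GGLHMFTPDYQCVFIPHVAHDNKSK
>ANXA13|NP_001003954|synthetic
QWKPDLHAEPETEKHVRGETYPKQTHSTLELHQQEGHTQHNPSFFQMFFNNYNLTAHCLG
RMYPKIRPINQQPQHPWTNAFTWWYPDQRCFHHEAQWLNVVEYQQDPGKDEQVAPLFFLA
WYMQAKYCCNVGPMFILMGEDYTCPYQPNHPMQVCVPFHNAIVALEKRCHLTPPRFYIQD
PTEVLAPQVVHRETVHCNRLIAQQSAGLEYHWLLMPQFATQKLYPMDCTSYRVLCVKMMM
FIMVVAQKEFVGVRAAFPIGFMCENNIADFVEIMLNCLGARQSTDQYNHNLMRVLPKLFQ
QCWNALMHQEYPQWTMMEEDLWMSTDVPVEWMPGSFMTNPHITNVLCPHPNVLNHSK
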